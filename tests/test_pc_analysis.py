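"""Proteome-constrained FVA, classification, metadata correlation,
and the representative model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pcgem import gem_core
from pcgem.pc_analysis import (
    CLASS_DEPENDENT,
    CLASS_INDEPENDENT,
    EnvelopeRecord,
    NoEnzymeEntityError,
    build_representative_model,
    classify_reactions,
    correlate_metadata,
    enzyme_abundance_range,
    pc_fva,
    spearman_rho,
)
from pcgem.proteome_fit import build_context_model

from _oracles import brute_spearman, extract_lp, linprog_minmax


@pytest.fixture(scope="module")
def context(pc_model, fitted_sample):
    _, _, fit = fitted_sample
    return build_context_model(pc_model, fit, s=0.03)


@pytest.fixture(scope="module")
def envelopes(context):
    return pc_fva(context, "NAKPUMP")


class TestPCFVA:
    def test_fraction_zero_equals_plain_fva(self, context, envelopes):
        table = gem_core.fva(context.model, fraction_of_optimum=0.0,
                             reactions=[r for r in envelopes])
        for rid, env in envelopes.items():
            lo, hi = env.ranges[0.0]
            assert lo == pytest.approx(table.loc[rid, "minimum"], abs=1e-6)
            assert hi == pytest.approx(table.loc[rid, "maximum"], abs=1e-6)

    def test_effective_envelope_is_union(self, envelopes):
        for env in envelopes.values():
            assert env.effective_min == min(lo for lo, _ in env.ranges.values())
            assert env.effective_max == max(hi for _, hi in env.ranges.values())

    def test_nesting_across_fractions(self, envelopes):
        for env in envelopes.values():
            for f1, f2 in [(0.0, 0.5), (0.5, 0.9), (0.9, 0.99)]:
                lo1, hi1 = env.ranges[f1]
                lo2, hi2 = env.ranges[f2]
                assert lo2 >= lo1 - 1e-6
                assert hi2 <= hi1 + 1e-6

    def test_matches_linprog_oracle_with_objective_fraction(self, context):
        model = context.model
        S, lb, ub, cols = extract_lp(model)
        j_obj = cols.index("NAKPUMP")
        obj = np.zeros(len(cols))
        obj[j_obj] = 1.0
        _, opt = linprog_minmax(S, lb, ub, obj)
        fraction = 0.9
        # encode objective >= fraction * opt as an extra <= row
        extra_A = -obj[None, :]
        extra_b = np.array([-fraction * opt])
        envelopes = pc_fva(context, "NAKPUMP", fractions=(fraction,),
                           reactions=["GLYCL", "NAKPUMP", "LACT", "GLGS"])
        for rid, env in envelopes.items():
            sel = np.zeros(len(cols))
            sel[cols.index(rid)] = 1.0
            lo, hi = linprog_minmax(S, lb, ub, sel, extra_A=extra_A, extra_b=extra_b)
            got_lo, got_hi = env.ranges[fraction]
            assert got_lo == pytest.approx(lo, abs=1e-6)
            assert got_hi == pytest.approx(hi, abs=1e-6)


class TestEnzymeAbundance:
    def test_matches_linprog_oracle(self, context):
        model = context.model
        S, lb, ub, cols = extract_lp(model)
        for rid in ("NAKPUMP", "GLGS", "LACT"):
            obj = np.zeros(len(cols))
            obj[cols.index(f"ENZFM_{rid}")] = 1.0
            if f"ENZRM_{rid}" in cols:
                obj[cols.index(f"ENZRM_{rid}")] = 1.0
            lo, hi = linprog_minmax(S, lb, ub, obj)
            got = enzyme_abundance_range(context, rid)
            assert got[0] == pytest.approx(lo, abs=1e-6)
            assert got[1] == pytest.approx(hi, abs=1e-6)

    def test_spontaneous_reaction_has_no_entity(self, context):
        with pytest.raises(NoEnzymeEntityError):
            enzyme_abundance_range(context, "ATPM")

    def test_pinned_protein_with_s_zero(self, pc_model, fitted_sample):
        _, _, fit = fitted_sample
        ctx = build_context_model(pc_model, fit, s=0.0)
        # pick a single-subunit enzyme whose protein was measured
        candidates = {"HEX": "HK1", "GLGS": "GYS1", "KLEAK": "KCNN4"}
        rid, gene = next(
            (r, g) for r, g in candidates.items() if not pd.isna(fit.p_data[g])
        )
        lo, hi = enzyme_abundance_range(ctx, rid)
        r = pc_model.kinetics.r_fwd[(rid, f"CPLX_{rid}_{gene}")]
        expected = r * fit.p_prime[gene]
        assert hi == pytest.approx(expected, rel=1e-6)

    def test_mass_bound(self, context):
        budget = context.pc.budget
        lightest = min(
            c.molar_mass(context.pc.proteins) for c in context.pc.complexes
        )
        _, hi = enzyme_abundance_range(context, "NAKPUMP")
        r_max = max(context.pc.kinetics.r_fwd.values())
        assert hi <= r_max * (budget.p_la_ub + context.p_r_ub) / lightest + 1e-6


class TestSpearman:
    def test_monotone_pairs(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 25, 100]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_constant_vector_undefined(self):
        assert np.isnan(spearman_rho([1, 1, 1], [1, 2, 3]))

    def test_short_vector_undefined(self):
        assert np.isnan(spearman_rho([1.0], [2.0]))

    def test_missing_pairs_dropped(self):
        rho = spearman_rho([1, 2, np.nan, 4], [1, 2, 99, 4])
        assert rho == pytest.approx(1.0)

    @given(
        st.lists(
            st.tuples(st.integers(-5, 5), st.integers(-5, 5)),
            min_size=2,
            max_size=50,
        )
    )
    def test_matches_rank_formula_oracle_with_ties(self, pairs):
        x = [p[0] for p in pairs]
        y = [p[1] for p in pairs]
        got = spearman_rho(x, y)
        expected = brute_spearman(x, y)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expected, abs=1e-12)


class TestClassification:
    @staticmethod
    def _tables():
        idx = [f"s{i}" for i in range(6)]
        flux = pd.DataFrame(
            {
                "R_dep": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "R_spont": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "R_blocked": [0.0] * 6,
                "R_uncorr": [1.0, 5.0, 2.0, 6.0, 3.0, 4.0],
            },
            index=idx,
        )
        abund = pd.DataFrame(
            {
                "R_dep": [10.0, 20.0, 30.0, 40.0, 50.0, 60.0],
                "R_spont": [np.nan] * 6,
                "R_blocked": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "R_uncorr": [6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
            },
            index=idx,
        )
        gprs = {"R_dep": "gA", "R_spont": "", "R_blocked": "gB", "R_uncorr": "gC"}
        return flux, abund, gprs

    def test_rules(self):
        flux, abund, gprs = self._tables()
        out = classify_reactions(flux, abund, blocked={"R_blocked"}, gprs=gprs)
        assert out.loc["R_dep", "classification"] == CLASS_DEPENDENT
        assert out.loc["R_dep", "rho"] == pytest.approx(1.0)
        assert out.loc["R_spont", "flag"] == "spontaneous"
        assert out.loc["R_spont", "classification"] == CLASS_INDEPENDENT
        assert out.loc["R_blocked", "flag"] == "blocked"
        assert out.loc["R_blocked", "classification"] == CLASS_INDEPENDENT
        assert out.loc["R_uncorr", "classification"] == CLASS_INDEPENDENT

    def test_classes_partition(self):
        flux, abund, gprs = self._tables()
        out = classify_reactions(flux, abund, blocked={"R_blocked"}, gprs=gprs)
        counts = out["classification"].value_counts()
        assert counts.sum() == len(flux.columns)

    def test_misaligned_samples_rejected(self):
        flux, abund, gprs = self._tables()
        with pytest.raises(ValueError):
            classify_reactions(flux, abund.iloc[::-1], blocked=set(), gprs=gprs)


class TestMetadataCorrelation:
    def test_identical_column_correlates_perfectly(self):
        idx = [f"s{i}" for i in range(8)]
        values = pd.DataFrame({"v1": np.arange(8.0), "v2": [3, 1, 4, 1, 5, 9, 2, 6]}, index=idx)
        metadata = pd.DataFrame({"m1": np.arange(8.0), "m2": np.random.default_rng(0).normal(size=8)}, index=idx)
        corr, rows, cols = correlate_metadata(metadata, values)
        assert corr.loc["m1", "v1"] == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        idx = [f"s{i}" for i in range(8)]
        base = pd.Series([0.3, 1.2, 0.1, 2.2, 1.9, 0.7, 2.8, 0.5], index=idx)
        values = pd.DataFrame({"v": base})
        m1 = pd.DataFrame({"m": base})
        m2 = pd.DataFrame({"m": np.exp(3 * base)})
        c1, _, _ = correlate_metadata(m1, values)
        c2, _, _ = correlate_metadata(m2, values)
        assert c1.loc["m", "v"] == pytest.approx(c2.loc["m", "v"], abs=1e-12)

    def test_identical_rows_cluster_adjacent(self):
        idx = [f"s{i}" for i in range(10)]
        rng = np.random.default_rng(1)
        values = pd.DataFrame(rng.normal(size=(10, 4)), index=idx, columns=list("abcd"))
        metadata = pd.DataFrame(
            {"twin1": values["a"], "twin2": values["a"], "other": rng.normal(size=10)},
            index=idx,
        )
        corr, rows, _ = correlate_metadata(metadata, values)
        i, j = rows.index("twin1"), rows.index("twin2")
        assert abs(i - j) == 1

    def test_all_missing_column_dropped(self):
        idx = [f"s{i}" for i in range(5)]
        values = pd.DataFrame({"v": np.arange(5.0)}, index=idx)
        metadata = pd.DataFrame({"ok": np.arange(5.0), "empty": [np.nan] * 5}, index=idx)
        with pytest.warns(UserWarning, match="empty"):
            corr, rows, _ = correlate_metadata(metadata, values)
        assert "empty" not in corr.index


class TestRepresentativeModel:
    def test_single_context_identity(self, pc_model, envelopes):
        rep = build_representative_model(pc_model, [envelopes])
        for rid, env in envelopes.items():
            rxn = rep.model.reactions.get_by_id(rid)
            assert rxn.lower_bound == pytest.approx(env.effective_min, abs=1e-9)
            assert rxn.upper_bound == pytest.approx(env.effective_max, abs=1e-9)

    def test_componentwise_min_max_of_two_contexts(self, pc_model):
        e1 = {"GLGS": EnvelopeRecord("GLGS", {0.0: (-1.0, 2.0)})}
        e2 = {"GLGS": EnvelopeRecord("GLGS", {0.0: (-0.5, 3.0)})}
        rep = build_representative_model(pc_model, [e1, e2])
        rxn = rep.model.reactions.get_by_id("GLGS")
        assert rxn.bounds == (-1.0, 3.0)

    def test_contexts_contained_in_representative(self, pc_model, envelopes):
        rep = build_representative_model(pc_model, [envelopes])
        for rid, env in envelopes.items():
            rxn = rep.model.reactions.get_by_id(rid)
            for lo, hi in env.ranges.values():
                assert rxn.lower_bound <= lo + 1e-9
                assert rxn.upper_bound >= hi + -1e-9

    def test_empty_input_rejected(self, pc_model):
        with pytest.raises(ValueError):
            build_representative_model(pc_model, [])

    def test_protein_bounds_from_abundance_ranges(self, pc_model, envelopes):
        ranges1 = {"GYS1": (1.0, 5.0)}
        ranges2 = {"GYS1": (2.0, 9.0)}
        rep = build_representative_model(pc_model, [envelopes, envelopes], [ranges1, ranges2])
        rxn = rep.model.reactions.get_by_id(rep.dilution_id("GYS1"))
        assert rxn.bounds == (1.0, 9.0)
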