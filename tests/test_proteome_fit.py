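"""Sample preparation, budget normalization, QP fitting, context
models, and slack calibration."""

import math

import numpy as np
import pandas as pd
import pytest

from pcgem.pc_build import (
    NMOL_TO_MMOL,
    PREFIX,
    BudgetConfig,
    ComplexRecord,
    Kinetics,
    ProteinRecord,
    build_pc_model,
)
from pcgem.proteome_fit import (
    ProteomeSample,
    build_context_model,
    calibrate_slack,
    fit_proteome,
    normalize_to_budget,
    prepare_samples,
)

from _oracles import kkt_qp_nonneg_budget


class TestPrepareSamples:
    @staticmethod
    def _raw(columns):
        return pd.DataFrame(
            {c: [1.0, 2.0] for c in columns}, index=["ACC1", "ACC2"]
        )

    def test_incomplete_donor_dropped(self):
        raw = self._raw(["d1_10", "d1_23", "d1_42", "d2_10", "d2_23"])
        hb = pd.DataFrame({"donor_id": ["d1", "d2"], "hb_concentration": [13.0, 14.0]})
        samples = prepare_samples(raw, hb)
        assert {s.donor_id for s in samples} == {"d1"}
        assert len(samples) == 3

    def test_missing_hb_imputed_with_donor_mean(self):
        raw = self._raw(["d1_10", "d1_23", "d1_42", "d2_10", "d2_23", "d2_42"])
        hb = pd.DataFrame({"donor_id": ["d1", "d2"], "hb_concentration": [np.nan, 14.0]})
        samples = prepare_samples(raw, hb)
        d1 = [s for s in samples if s.donor_id == "d1"][0]
        assert d1.hb_concentration == pytest.approx(14.0)
        # total protein approach: intensities scaled by hemoglobin conc
        assert d1.p_data["ACC1"] == pytest.approx(1.0 * 14.0)

    def test_unknown_donor_rejected(self):
        raw = self._raw(["dX_10"])
        hb = pd.DataFrame({"donor_id": ["d1"], "hb_concentration": [13.0]})
        with pytest.raises(ValueError, match="unknown donor"):
            prepare_samples(raw, hb)

    def test_sample_count_three_per_donor(self, small_panel):
        samples = small_panel["samples"]
        assert len(samples) == 3 * small_panel["spec"].n_donors


class TestNormalizeToBudget:
    def test_hemoglobin_mass_fraction(self, pc_model, small_panel):
        sample = small_panel["samples"][0]
        vec = normalize_to_budget(sample, pc_model)
        masses = {g: pc_model.proteins[g].molar_mass for g in pc_model.proteins}
        hb_mass = sum(vec[g] * masses[g] for g in pc_model.hb_genes)
        la_mass = sum(
            vec[g] * masses[g]
            for g in pc_model.proteins
            if g not in pc_model.hb_genes and not pd.isna(vec[g])
        )
        assert hb_mass == pytest.approx(950.0, rel=1e-9)
        assert la_mass == pytest.approx(50.0, rel=1e-9)
        assert hb_mass / (hb_mass + la_mass) == pytest.approx(0.95, abs=1e-12)

    def test_scale_invariance(self, pc_model, small_panel):
        sample = small_panel["samples"][0]
        doubled = ProteomeSample(
            sample.donor_id, sample.storage_day, sample.p_data * 2.0, sample.hb_concentration
        )
        a = normalize_to_budget(sample, pc_model)
        b = normalize_to_budget(doubled, pc_model)
        pd.testing.assert_series_equal(a, b)

    def test_missing_stays_missing(self, pc_model, small_panel):
        for sample in small_panel["samples"]:
            masked = sample.p_data.isna()
            if not masked.any():
                continue
            vec = normalize_to_budget(sample, pc_model)
            acc2gene = pc_model.accession_to_gene
            for acc in sample.p_data.index[masked]:
                if acc in acc2gene:
                    assert pd.isna(vec[acc2gene[acc]])
            return
        pytest.skip("panel had no masked model protein")

    def test_no_hb_signal_rejected(self, pc_model):
        p = pd.Series({acc: 1.0 for acc in pc_model.accession_to_gene})
        hb_accs = [
            rec.accession for rec in pc_model.proteins.values() if rec.is_hemoglobin
        ]
        p[hb_accs] = np.nan
        sample = ProteomeSample("dX", 10, p, 13.0)
        with pytest.raises(ValueError, match="hemoglobin"):
            normalize_to_budget(sample, pc_model)


class TestFitProteome:
    def test_feasible_target_recovered_exactly(self, pc_model, fitted_sample):
        _, p_data, fit = fitted_sample
        assert fit.status == "optimal"
        assert fit.objective_value < 1e-10
        measured = p_data.dropna()
        err = (fit.p_prime[measured.index] - measured).abs() / measured.clip(lower=1e-9)
        assert float(err.max()) < 1e-6

    def test_missing_weight_zero(self, pc_model, fitted_sample):
        _, p_data, fit = fitted_sample
        missing = p_data.index[p_data.isna()]
        assert (fit.weights[missing] == 0.0).all()

    def test_order_invariance(self, pc_model, fitted_sample):
        _, p_data, fit = fitted_sample
        shuffled = p_data.iloc[::-1]
        fit2 = fit_proteome(pc_model, shuffled)
        assert fit2.objective_value == pytest.approx(fit.objective_value, abs=1e-9)
        pd.testing.assert_series_equal(fit.p_prime, fit2.p_prime, atol=1e-6, rtol=1e-6)

    def test_matches_kkt_active_set_oracle(self, chain):
        # A model with no enzymatic coupling: the QP reduces to
        # min sum c (p - d)^2  s.t.  sum p w <= LA budget, p >= 0
        genes = ["gA", "gB", "gC", "gD", "gE"]
        w = np.array([0.05, 0.02, 0.08, 0.04, 0.10])
        proteins = [ProteinRecord(g, f"P{g}", wi) for g, wi in zip(genes, w)]
        kin = Kinetics({}, {}, {}, {}, 2.34e5)
        budget = BudgetConfig(p_hb_lb=0.0, p_la_ub=100.0)
        pcm = build_pc_model(chain, proteins, [], kinetics=kin, budget=budget)
        d = np.array([800.0, 900.0, 200.0, 0.0, 150.0])  # mass 94 > 50 cap
        p_data = pd.Series(d, index=genes)
        fit = fit_proteome(pcm, p_data)
        c = np.array([1.0 / di if di > 0 else 1.0 for di in d])
        oracle_p, oracle_obj = kkt_qp_nonneg_budget(c, d, w, budget=50.0)
        assert fit.objective_value == pytest.approx(oracle_obj, rel=1e-6, abs=1e-8)
        np.testing.assert_allclose(
            fit.p_prime[genes].to_numpy(), oracle_p, rtol=1e-5, atol=1e-6
        )

    def test_summary_is_informative(self, fitted_sample):
        _, _, fit = fitted_sample
        text = fit.summary()
        assert "objective" in text and "proteins" in text


class TestContextModel:
    def test_s_zero_pins_everything(self, pc_model, fitted_sample):
        _, p_data, fit = fitted_sample
        ctx = build_context_model(pc_model, fit, s=0.0)
        assert ctx.p_r_ub == 0.0
        for gene in pc_model.proteins:
            lo, hi = ctx.protein_abundance_range(gene)
            if pd.isna(fit.p_data[gene]):
                assert hi == pytest.approx(0.0, abs=1e-9)
            else:
                assert lo == pytest.approx(fit.p_prime[gene], rel=1e-6, abs=1e-9)
                assert hi == pytest.approx(fit.p_prime[gene], rel=1e-6, abs=1e-9)

    def test_relaxation_budget_size(self, pc_model, fitted_sample):
        _, _, fit = fitted_sample
        s = 0.03
        ctx = build_context_model(pc_model, fit, s=s)
        fitted_mass = sum(
            fit.p_prime[g] * pc_model.proteins[g].molar_mass for g in pc_model.proteins
        )
        assert ctx.p_r_ub == pytest.approx(s * fitted_mass, rel=1e-9)

    def test_default_slack_is_three_percent(self, pc_model, fitted_sample):
        _, _, fit = fitted_sample
        ctx = build_context_model(pc_model, fit)
        assert ctx.slack == 0.03

    def test_bound_structure_follows_slack_formula(self, pc_model, fitted_sample):
        _, _, fit = fitted_sample
        s = 0.05
        ctx = build_context_model(pc_model, fit, s=s)
        for gene, rec in pc_model.proteins.items():
            lo, hi = ctx.protein_abundance_range(gene)
            relax_cap = s * ctx.p_r_ub / rec.molar_mass
            if pd.isna(fit.p_data[gene]):
                assert lo >= -1e-9
                assert hi <= relax_cap + 1e-6
            else:
                p = fit.p_prime[gene]
                assert lo >= (1 - s) * p - 1e-6
                assert hi <= p + relax_cap + 1e-6

    def test_feasible_region_grows_with_slack(self, pc_model, fitted_sample):
        _, _, fit = fitted_sample
        objs = []
        for s in (0.0, 0.03, 0.1):
            ctx = build_context_model(pc_model, fit, s=s)
            objs.append(ctx.optimize("NAKPUMP").objective_value)
        assert objs == sorted(objs)

    def test_negative_slack_rejected(self, pc_model, fitted_sample):
        _, _, fit = fitted_sample
        with pytest.raises(ValueError):
            build_context_model(pc_model, fit, s=-0.1)

    def test_mass_conservation_with_relaxation(self, pc_model, fitted_sample):
        _, _, fit = fitted_sample
        ctx = build_context_model(pc_model, fit, s=0.03)
        sol = ctx.optimize("NAKPUMP")
        total = sum(
            (sol.fluxes[ctx.pc.dilution_id(g)] + sol.fluxes[ctx.pc.relax_id(g)])
            * pc_model.proteins[g].molar_mass
            for g in pc_model.proteins
        )
        pools = (
            sol.fluxes[PREFIX["pool_hb"]]
            + sol.fluxes[PREFIX["pool_la"]]
            + sol.fluxes[PREFIX["pool_relax"]]
        )
        assert total == pytest.approx(pools, abs=1e-6)


class TestCalibrateSlack:
    def test_feasible_at_zero_returns_smallest(self, toy_model, protein_tables, fitted_sample):
        # generous turnover and a fully measured proteome: the
        # objective plateaus already at zero slack
        proteins, complexes = protein_tables
        budget = BudgetConfig(p_hb_lb=0.0, p_la_ub=100.0, k_avg=1e10)
        pcm = build_pc_model(toy_model, proteins, complexes, budget=budget)
        sample, _, _ = fitted_sample
        full = ProteomeSample(
            sample.donor_id,
            sample.storage_day,
            sample.p_data.fillna(sample.p_data.dropna().median()),
            sample.hb_concentration,
        )
        fit = fit_proteome(pcm, normalize_to_budget(full, pcm))
        cal = calibrate_slack(pcm, [fit], "NAKPUMP", s_grid=(0.0, 0.05, 0.1))
        assert cal.slack == 0.0

    def test_objective_nondecreasing_in_slack(self, pc_model, fitted_sample):
        _, _, fit = fitted_sample
        cal = calibrate_slack(pc_model, [fit], "NAKPUMP", s_grid=(0.0, 0.03, 0.1))
        objs = cal.table.sort_values("s")["objective"].to_numpy()
        assert np.all(np.diff(objs) >= -1e-9)

    def test_matches_exhaustive_sweep(self, pc_model, fitted_sample):
        _, _, fit = fitted_sample
        grid = (0.0, 0.02, 0.05, 0.1)
        cal = calibrate_slack(pc_model, [fit], "NAKPUMP", s_grid=grid)
        # brute-force re-evaluation of the plateau rule
        objs = {
            s: build_context_model(pc_model, fit, s=s).optimize("NAKPUMP").objective_value
            for s in grid
        }
        plateau = objs[grid[-1]]
        expected = next(
            (s for s in grid if objs[s] >= 0.99 * plateau - 1e-12), grid[-1]
        )
        assert cal.slack == expected
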