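"""Proteome-constrained flux variability analysis and reaction
classification by abundance dependence.

For each context-specific model the flux of every reaction is bounded
while the objective reaction (e.g. the Na+/K+-ATPase) is constrained
to 0%, 50%, 90% and 99% of its maximum; the *effective* envelope is
the union of the per-fraction ranges.  Across samples, the Spearman
rank correlation between a reaction's maximum flux and the abundance
of its 'enzyme' entity classifies the reaction as

* abundance-dependent  (rho >= 0.8),
* abundance-correlated (0.5 <= rho < 0.8),
* abundance-independent (rho < 0.5),

with spontaneous (GPR-free) and blocked reactions always
abundance-independent.  Donor metadata columns are correlated with the
same per-sample quantities and ordered by hierarchical clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import cobra
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .gem_core import fva as _fva
from .pc_build import PREFIX, PCModel
from .proteome_fit import ContextModel

__all__ = [
    "DEPENDENT_RHO",
    "CORRELATED_RHO",
    "EnvelopeRecord",
    "pc_fva",
    "enzyme_abundance_range",
    "spearman_rho",
    "classify_reactions",
    "correlate_metadata",
    "build_representative_model",
]

DEPENDENT_RHO = 0.8
CORRELATED_RHO = 0.5

CLASS_DEPENDENT = "abundance-dependent"
CLASS_CORRELATED = "abundance-correlated"
CLASS_INDEPENDENT = "abundance-independent"


class NoEnzymeEntityError(KeyError):
    """The reaction has no gene association, hence no enzyme entity."""


@dataclass
class EnvelopeRecord:
    """Per-reaction flux ranges across objective fractions.

    ``ranges`` maps objective fraction to (min, max); the effective
    envelope is the union over fractions.
    """

    reaction_id: str
    ranges: dict[float, tuple[float, float]] = field(default_factory=dict)

    @property
    def effective_min(self) -> float:
        return min(lo for lo, _ in self.ranges.values())

    @property
    def effective_max(self) -> float:
        return max(hi for _, hi in self.ranges.values())


def pc_fva(
    context: ContextModel | PCModel,
    objective_reaction: str,
    fractions: Sequence[float] = (0.0, 0.5, 0.9, 0.99),
    reactions: Sequence[str] | None = None,
) -> dict[str, EnvelopeRecord]:
    """Proteome-constrained FVA at several objective fractions.

    At fraction 0 this is plain FVA on the context model.  A fraction
    at which the constrained problem turns out infeasible (possible
    only through numeric tolerance) is skipped with a warning.
    """
    model = context.model
    pc = context.pc if isinstance(context, ContextModel) else context
    if reactions is None:
        reactions = [r for r in pc.base_reaction_ids() if r in model.reactions]
    records = {r: EnvelopeRecord(r) for r in reactions}
    for fraction in fractions:
        try:
            with model:
                model.objective = model.reactions.get_by_id(objective_reaction)
                model.objective_direction = "max"
                table = _fva(model, fraction_of_optimum=fraction, reactions=reactions)
        except Exception as exc:  # pragma: no cover - numeric edge
            warnings.warn(f"pc_fva infeasible at fraction {fraction}: {exc}")
            continue
        for rid in reactions:
            records[rid].ranges[fraction] = (
                float(table.loc[rid, "minimum"]),
                float(table.loc[rid, "maximum"]),
            )
    return records


def enzyme_abundance_range(context: ContextModel | PCModel, reaction_id: str) -> tuple[float, float]:
    """Attainable total 'enzyme' abundance e_fwd + e_rev for a reaction.

    Raises :class:`NoEnzymeEntityError` for reactions without gene
    association (no enzyme entity exists).
    """
    model = context.model
    pc = context.pc if isinstance(context, ContextModel) else context
    fwd = pc.enzyme_fwd_id(reaction_id)
    rev = pc.enzyme_rev_id(reaction_id)
    if fwd not in model.reactions:
        raise NoEnzymeEntityError(f"reaction {reaction_id} has no enzyme entity")
    members = [fwd] + ([rev] if rev in model.reactions else [])
    out = []
    for direction in ("min", "max"):
        with model:
            model.objective = {model.reactions.get_by_id(r): 1.0 for r in members}
            model.objective_direction = direction
            sol = model.optimize(raise_error=False)
            if sol.status != "optimal":
                raise RuntimeError(f"enzyme abundance {direction} failed: {sol.status}")
            out.append(float(sol.objective_value))
    return out[0], out[1]


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with pairwise missing-value removal.

    Returns NaN (undefined) when fewer than two complete pairs remain
    or either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(x, y).statistic
    return float(rho)


def classify_reactions(
    flux_maxima: pd.DataFrame,
    abundances: pd.DataFrame,
    blocked: Iterable[str],
    gprs: Mapping[str, str],
    categories: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Classify reactions by Spearman correlation of max flux vs enzyme abundance.

    ``flux_maxima`` and ``abundances`` are samples x reactions tables
    aligned on the same sample index.  Spontaneous reactions (empty
    GPR) and blocked reactions are forced abundance-independent;
    undefined correlations (constant vectors) fall back to
    abundance-independent with a flag.
    """
    if not flux_maxima.index.equals(abundances.index):
        raise ValueError("flux and abundance tables must share the same sample index")
    blocked = set(blocked)
    rows = []
    for rid in flux_maxima.columns:
        gpr = (gprs.get(rid) or "").strip()
        category = (categories or {}).get(rid, "")
        if not gpr:
            rows.append((rid, np.nan, CLASS_INDEPENDENT, category, "spontaneous"))
            continue
        if rid in blocked:
            rows.append((rid, np.nan, CLASS_INDEPENDENT, category, "blocked"))
            continue
        rho = spearman_rho(flux_maxima[rid].to_numpy(), abundances[rid].to_numpy())
        if np.isnan(rho):
            rows.append((rid, rho, CLASS_INDEPENDENT, category, "undefined-rho"))
        elif rho >= DEPENDENT_RHO:
            rows.append((rid, rho, CLASS_DEPENDENT, category, ""))
        elif rho >= CORRELATED_RHO:
            rows.append((rid, rho, CLASS_CORRELATED, category, ""))
        else:
            rows.append((rid, rho, CLASS_INDEPENDENT, category, ""))
    df = pd.DataFrame(rows, columns=["reaction_id", "rho", "classification", "category", "flag"])
    return df.set_index("reaction_id")


def group_proteins_by_reaction_sets(
    classification: pd.DataFrame, gene_reactions: Mapping[str, set[str]]
) -> pd.DataFrame:
    """Group proteins whose associated reaction sets are identical.

    Returns one row per protein group with the member genes, the
    shared reaction set, and the count of abundance-dependent
    reactions in that set.
    """
    dependent = set(classification.index[classification["classification"] == CLASS_DEPENDENT])
    by_sig: dict[frozenset[str], list[str]] = {}
    for gene, rxns in gene_reactions.items():
        by_sig.setdefault(frozenset(rxns), []).append(gene)
    rows = []
    for sig, genes in by_sig.items():
        rows.append(
            {
                "genes": ";".join(sorted(genes)),
                "n_reactions": len(sig),
                "n_dependent": len(sig & dependent),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["n_dependent", "genes"], ascending=[False, True])
        .reset_index(drop=True)
    )


def correlate_metadata(
    metadata: pd.DataFrame,
    values: pd.DataFrame,
    linkage_method: str = "average",
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Spearman correlations between metadata columns and value columns.

    Shared samples are aligned on the index; all-missing metadata
    columns are dropped with a warning.  Rows and columns of the
    correlation matrix are ordered by agglomerative clustering with
    Euclidean distance on the correlation vectors; the reordered
    matrix and the orders are returned.
    """
    shared = metadata.index.intersection(values.index)
    if len(shared) < 2:
        raise ValueError("need at least two shared samples")
    meta = metadata.loc[shared].apply(pd.to_numeric, errors="coerce")
    vals = values.loc[shared]
    empty = [c for c in meta.columns if meta[c].notna().sum() == 0]
    if empty:
        warnings.warn(f"dropping all-missing metadata columns: {empty}")
        meta = meta.drop(columns=empty)
    corr = pd.DataFrame(
        {
            vcol: {mcol: spearman_rho(meta[mcol], vals[vcol]) for mcol in meta.columns}
            for vcol in vals.columns
        }
    )
    corr = corr.loc[list(meta.columns), list(vals.columns)]
    row_order = _cluster_order(corr.fillna(0.0).to_numpy(), linkage_method)
    col_order = _cluster_order(corr.fillna(0.0).to_numpy().T, linkage_method)
    rows = [corr.index[i] for i in row_order]
    cols = [corr.columns[j] for j in col_order]
    return corr.loc[rows, cols], rows, cols


def _cluster_order(matrix: np.ndarray, method: str) -> list[int]:
    if matrix.shape[0] < 2:
        return list(range(matrix.shape[0]))
    link = hierarchy.linkage(matrix, method=method, metric="euclidean")
    return list(hierarchy.leaves_list(link))


@dataclass
class SampleAnalyses:
    """Bundle of per-sample context analyses over one proteome panel.

    ``flux_maxima`` and ``abundance_maxima`` are samples x reactions;
    ``classification`` the per-reaction record; ``envelopes`` the full
    per-sample envelope records; ``protein_ranges`` per-sample
    attainable protein abundance (min, max) tables.
    """

    flux_maxima: pd.DataFrame
    abundance_maxima: pd.DataFrame
    classification: pd.DataFrame
    blocked: set[str]
    fits: list
    envelopes: list[dict[str, EnvelopeRecord]]
    protein_ranges: list[dict[str, tuple[float, float]]]


def analyze_samples(
    pc_model: PCModel,
    samples: Sequence,
    objective_reaction: str,
    slack: float | None = None,
    fractions: Sequence[float] = (0.0, 0.5, 0.9, 0.99),
    reactions: Sequence[str] | None = None,
    protein_ranges: bool = False,
) -> SampleAnalyses:
    """Fit every sample, build its context model, and classify reactions.

    For each sample the proteome is budget-normalized and fitted, the
    slack-relaxed context model built, proteome-constrained FVA run
    with the given objective reaction, and the maximum attainable
    'enzyme' abundance computed per enzymatic reaction.  The per-sample
    maxima feed the Spearman classification.  The effective maximum
    flux is attained at objective fraction 0, so passing
    ``fractions=(0.0,)`` yields the identical classification faster.
    """
    from .gem_core import find_blocked
    from .proteome_fit import build_context_model, fit_proteome, normalize_to_budget

    if reactions is None:
        reactions = pc_model.base_reaction_ids()
    enzymatic = [r for r in pc_model.enzymatic_reactions if r in set(reactions)]
    blocked = find_blocked(pc_model.base_model)
    flux_rows, abund_rows, ids = [], [], []
    fits, env_list, prot_ranges = [], [], []
    for sample in samples:
        p_data = normalize_to_budget(sample, pc_model)
        fit = fit_proteome(pc_model, p_data)
        ctx = build_context_model(pc_model, fit, s=slack)
        env = pc_fva(ctx, objective_reaction, fractions=fractions, reactions=reactions)
        flux_rows.append({r: env[r].effective_max for r in reactions})
        abund_rows.append({r: enzyme_abundance_range(ctx, r)[1] for r in enzymatic})
        ids.append(sample.sample_id)
        fits.append(fit)
        env_list.append(env)
        if protein_ranges:
            prot_ranges.append({g: ctx.protein_abundance_range(g) for g in pc_model.proteins})
    flux_df = pd.DataFrame(flux_rows, index=ids)
    abund_df = pd.DataFrame(abund_rows, index=ids).reindex(columns=flux_df.columns)
    categories = {r.id: (r.subsystem or "") for r in pc_model.base_model.reactions}
    gprs = {r.id: r.gene_reaction_rule for r in pc_model.base_model.reactions}
    classification = classify_reactions(flux_df, abund_df, blocked, gprs, categories)
    return SampleAnalyses(flux_df, abund_df, classification, blocked, fits, env_list, prot_ranges)


def build_representative_model(
    pc_model: PCModel,
    envelopes: Sequence[Mapping[str, EnvelopeRecord]],
    abundance_ranges: Sequence[Mapping[str, tuple[float, float]]] | None = None,
) -> PCModel:
    """Fold per-context envelopes into one representative model.

    Reaction bounds become the componentwise (min of effective minima,
    max of effective maxima) across contexts; protein dilution bounds
    are set likewise from per-protein abundance ranges when given.
    """
    if not envelopes:
        raise ValueError("need at least one context's envelopes")
    rep = pc_model.copy()
    rxn_ids = set(envelopes[0])
    for env in envelopes[1:]:
        rxn_ids &= set(env)
    for rid in sorted(rxn_ids):
        lo = min(env[rid].effective_min for env in envelopes)
        hi = max(env[rid].effective_max for env in envelopes)
        rep.model.reactions.get_by_id(rid).bounds = (lo, hi)
    if abundance_ranges:
        genes = set(abundance_ranges[0])
        for table in abundance_ranges[1:]:
            genes &= set(table)
        for gene in sorted(genes):
            lo = min(t[gene][0] for t in abundance_ranges)
            hi = max(t[gene][1] for t in abundance_ranges)
            rep.model.reactions.get_by_id(rep.dilution_id(gene)).bounds = (lo, hi)
    return rep
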