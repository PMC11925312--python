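"""Proteome normalization, quadratic-programming fitting, and
context-specific model construction.

The measured proteome of one sample is mapped onto the model proteins,
budget-scaled (hemoglobin mass to the hemoglobin pool cap, the rest to
the low-abundance cap), and fitted against the proteome-constrained
model by solving the convex QP

    minimize   sum_j c_j (p_j - p_j^data)^2
    subject to all proteome-constrained model constraints,

with inverse-abundance weights: c_j = 1/p_j^data for measured nonzero
values, 1 for measured zeros (penalizing expression of unobserved
proteins), and 0 for missing values (NaN), which leave the fitted
abundance unconstrained by the objective.  The best-fit vector p'
then defines a context-specific model whose protein bounds are relaxed
by a slack fraction ``s`` through a variable "relaxation" budget P_R —
a pool of unspecified protein mass absorbing measurement uncertainty:

    P_total = P_HB + P_LA + P_R,      0 <= P_R <= P_R_ub = s * sum_j p'_j w_j
    measured:   (1-s) p'_j <= p_j <= p'_j + s P_R_ub / w_j
    unmeasured:          0 <= p_j <= s P_R_ub / w_j

The slack is calibrated on representative (mean/median) samples by a
lexicographic criterion: maximize the flux of a target reaction, then
minimize the relaxation budget actually used, choosing the smallest
slack whose objective reaches the plateau across calibration models.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import cobra
import numpy as np
import osqp
import pandas as pd
from scipy import sparse

from .gem_core import FluxSolution, fba
from .pc_build import NMOL_TO_MMOL, PREFIX, BudgetConfig, PCModel

__all__ = [
    "ProteomeSample",
    "FitResult",
    "ContextModel",
    "CalibrationResult",
    "prepare_samples",
    "normalize_to_budget",
    "fit_proteome",
    "build_context_model",
    "calibrate_slack",
]


@dataclass
class ProteomeSample:
    """One donor x storage-day abundance vector.

    ``p_data`` maps UniProtKB accession to abundance; missing values
    are NaN and are distinct from measured zeros.  ``hb_concentration``
    is the donor hemoglobin at donation (g/dL), used by the total
    protein approach to convert relative intensities to copy numbers.
    """

    donor_id: str
    storage_day: int
    p_data: pd.Series
    hb_concentration: float

    @property
    def sample_id(self) -> str:
        return f"{self.donor_id}_{self.storage_day}"

    def __post_init__(self) -> None:
        vals = self.p_data.dropna()
        if (vals < 0).any():
            raise ValueError(f"sample {self.sample_id}: negative abundances")


@dataclass
class FitResult:
    """Best-fit proteome from the quadratic program.

    ``p_prime`` is the fitted abundance per gene (nmol/gDW);
    ``objective_value`` the attained weighted squared error;
    ``fluxes`` the full solution vector over the augmented model.
    """

    p_prime: pd.Series
    objective_value: float
    status: str
    p_data: pd.Series
    fluxes: pd.Series
    weights: pd.Series

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def summary(self) -> str:
        measured = self.p_data.notna()
        lines = [
            "Proteome fit",
            "=" * 40,
            f"status:            {self.status}",
            f"objective (wSSE):  {self.objective_value:.6g}",
            f"proteins:          {len(self.p_prime)}",
            f"measured:          {int(measured.sum())}",
            f"missing:           {int((~measured).sum())}",
        ]
        dev = (self.p_prime - self.p_data).abs().dropna().sort_values(ascending=False)
        if len(dev):
            lines.append("largest |p' - p_data| (nmol/gDW):")
            for gene, d in dev.head(5).items():
                lines.append(f"  {gene:<12s} {d:.4g}")
        return "\n".join(lines)


def fitted_mass(fit: FitResult, pc_model: PCModel) -> float:
    """Total fitted proteome mass sum_j p'_j w_j in mg/gDW."""
    return float(
        sum(fit.p_prime[g] * pc_model.proteins[g].molar_mass for g in fit.p_prime.index)
    )


# ---------------------------------------------------------------------------
# Sample preparation (total protein approach)
# ---------------------------------------------------------------------------

def prepare_samples(
    raw_matrix: pd.DataFrame,
    hb_table: pd.DataFrame,
    storage_days: Sequence[int] = (10, 23, 42),
) -> list[ProteomeSample]:
    """Turn a raw abundance matrix into per-sample copy-number vectors.

    ``raw_matrix`` has accessions as rows and sample ids
    ``<donor>_<day>`` as columns; ``hb_table`` has columns
    ``donor_id, hb_concentration``.  Donors missing any storage day are
    dropped; missing hemoglobin concentrations are imputed with the
    mean over the other donors; each sample is scaled by its donor's
    hemoglobin concentration (total protein approach).
    """
    hb = hb_table.set_index("donor_id")["hb_concentration"].astype(float)
    donors_days: dict[str, set[int]] = {}
    parsed: dict[str, tuple[str, int]] = {}
    for col in raw_matrix.columns:
        donor, _, day = str(col).rpartition("_")
        if not donor:
            raise ValueError(f"sample id {col!r} is not of the form <donor>_<day>")
        if donor not in hb.index:
            raise ValueError(f"sample {col!r}: unknown donor {donor!r}")
        parsed[col] = (donor, int(day))
        donors_days.setdefault(donor, set()).add(int(day))
    keep = {d for d, days in donors_days.items() if set(storage_days) <= days}
    hb_mean = hb.loc[sorted(keep)].dropna().mean()
    samples = []
    for col in raw_matrix.columns:
        donor, day = parsed[col]
        if donor not in keep or day not in storage_days:
            continue
        conc = hb.loc[donor]
        if pd.isna(conc):
            conc = hb_mean
        samples.append(
            ProteomeSample(donor, day, raw_matrix[col].astype(float) * float(conc), float(conc))
        )
    samples.sort(key=lambda s: (s.donor_id, s.storage_day))
    return samples


def normalize_to_budget(
    sample: ProteomeSample,
    pc_model: PCModel,
    budget: BudgetConfig | None = None,
) -> pd.Series:
    """Budget-scale one sample onto the model proteins.

    Hemoglobin abundances are rescaled so their mass totals the
    hemoglobin pool cap (950 mg/gDW in fitting mode), the remaining
    measured proteins so their mass totals the low-abundance cap
    (50 mg/gDW); within-group proportions are preserved.  Accessions
    absent from the model are ignored; missing stays missing (NaN).
    Returns a series indexed by gene symbol in nmol/gDW.
    """
    budget = (budget or pc_model.budget).fitting_mode()
    acc2gene = pc_model.accession_to_gene
    out = pd.Series(np.nan, index=sorted(pc_model.proteins), dtype=float)
    for acc, value in sample.p_data.items():
        gene = acc2gene.get(str(acc))
        if gene is not None:
            out[gene] = value
    hb_genes = pc_model.hb_genes
    masses = pd.Series({g: pc_model.proteins[g].molar_mass for g in out.index})
    is_hb = out.index.isin(hb_genes)
    measured = out.notna()

    hb_mass = float((out[measured & is_hb] * masses[measured & is_hb]).sum())
    if hb_mass <= 0:
        raise ValueError(f"sample {sample.sample_id}: no hemoglobin signal to scale")
    out[is_hb] = out[is_hb] * (budget.p_hb_ub / hb_mass)

    la_mask = measured & ~is_hb
    la_mass = float((out[la_mask] * masses[la_mask]).sum())
    if la_mass > 0:
        out[~is_hb] = out[~is_hb] * (budget.p_la_ub / la_mass)
    return out


# ---------------------------------------------------------------------------
# QP fit
# ---------------------------------------------------------------------------

def _qp_weights(pc_model: PCModel, p_data: pd.Series) -> pd.Series:
    weights = {}
    for gene in pc_model.proteins:
        d = p_data.get(gene, np.nan)
        if pd.isna(d):
            weights[gene] = 0.0
        elif d > 0:
            weights[gene] = 1.0 / float(d)
        else:
            weights[gene] = 1.0
    return pd.Series(weights)


def fit_proteome(
    pc_model: PCModel,
    p_data: pd.Series,
    budget: BudgetConfig | None = None,
    eps: float = 1e-12,
    max_iter: int = 400_000,
) -> FitResult:
    """Solve the weighted least-squares proteome fit as a sparse QP.

    ``p_data`` is indexed by gene symbol (budget-normalized,
    nmol/gDW); NaN marks missing proteins.  The fit runs with the
    fitting-mode budget bounds (hemoglobin/low-abundance caps 950/50)
    unless a budget override is given.  No metabolic flux objective is
    imposed during fitting.
    """
    budget = (budget or pc_model.budget).fitting_mode()
    model = pc_model.model
    weights = _qp_weights(pc_model, p_data)

    with model:
        model.reactions.get_by_id(PREFIX["pool_hb"]).bounds = (budget.p_hb_lb, budget.p_hb_ub)
        model.reactions.get_by_id(PREFIX["pool_la"]).bounds = (budget.p_la_lb, budget.p_la_ub)
        model.reactions.get_by_id(PREFIX["pool_total"]).bounds = (0.0, budget.p_total_ub)
        S = cobra.util.array.create_stoichiometric_matrix(model, array_type="lil").tocsc()
        lb = np.array([r.lower_bound for r in model.reactions])
        ub = np.array([r.upper_bound for r in model.reactions])
    rxn_index = {r.id: j for j, r in enumerate(model.reactions)}
    n = len(rxn_index)

    c = np.zeros(n)
    d = np.zeros(n)
    for gene, w in weights.items():
        j = rxn_index[pc_model.dilution_id(gene)]
        c[j] = w
        dv = p_data.get(gene, np.nan)
        d[j] = 0.0 if pd.isna(dv) else float(dv)

    # osqp solves 1/2 x'Px + q'x; our objective is sum c (x - d)^2.
    # Infinite bounds are boxed at +/-1e9 so the solver cannot emit a
    # spurious unboundedness certificate; the box is far beyond any
    # attainable flux or abundance.
    P = sparse.diags(2.0 * c, format="csc")
    q = -2.0 * c * d
    A = sparse.vstack([S, sparse.eye(n, format="csc")], format="csc")
    l = np.concatenate([np.zeros(S.shape[0]), np.maximum(lb, -1e9)])
    u = np.concatenate([np.zeros(S.shape[0]), np.minimum(ub, 1e9)])

    # The problem is posed in consistent units already; OSQP's heuristic
    # Ruiz scaling can stall on the pool/dilution structure, so solve
    # unscaled first and fall back to scaled / looser tolerances.
    res = None
    status = "failed"
    for attempt_eps, scaling in ((eps, 0), (max(eps, 1e-9), 0), (1e-7, 10)):
        solver = osqp.OSQP()
        solver.setup(
            P=P, q=q, A=A, l=l, u=u,
            verbose=False, eps_abs=attempt_eps, eps_rel=attempt_eps,
            max_iter=max_iter, polishing=True, scaling=scaling,
        )
        res = solver.solve()
        status = "optimal" if res.info.status == "solved" else res.info.status
        if status == "optimal":
            break
    x = np.asarray(res.x, dtype=float) if res.x is not None else np.full(n, np.nan)
    fluxes = pd.Series(x, index=[r.id for r in model.reactions])
    p_prime = pd.Series(
        {g: max(0.0, float(x[rxn_index[pc_model.dilution_id(g)]])) for g in pc_model.proteins}
    ).sort_index()
    data_aligned = pd.Series(
        {g: p_data.get(g, np.nan) for g in pc_model.proteins}, dtype=float
    ).sort_index()
    resid = (p_prime - data_aligned).fillna(0.0)
    objective = float((weights.sort_index() * resid**2).sum())
    return FitResult(p_prime, objective, status, data_aligned, fluxes, weights.sort_index())


# ---------------------------------------------------------------------------
# Context-specific models
# ---------------------------------------------------------------------------

@dataclass
class ContextModel:
    """A proteome-constrained model specialized to one fitted sample.

    ``model`` is the relaxed augmented COBRA model; ``p_r_ub`` the
    relaxation budget cap (mg/gDW); per-protein bounds follow the
    slack formulation in the module docstring.  The utilized
    relaxation budget is the flux of the ``PCPOOL_R`` pseudo-reaction.
    """

    model: cobra.Model
    pc: PCModel
    fit: FitResult
    slack: float
    p_r_ub: float

    def optimize(self, objective: str | None = None, sense: str = "max") -> FluxSolution:
        return fba(self.model, objective=objective, sense=sense)

    def protein_abundance_range(self, gene: str) -> tuple[float, float]:
        """Attainable total abundance (dilution + relaxation) of one protein."""
        return _optimize_sum(self.model, [self.pc.dilution_id(gene), self.pc.relax_id(gene)])

    def enzyme_abundance_range(self, reaction_id: str) -> tuple[float, float]:
        from .pc_analysis import enzyme_abundance_range

        return enzyme_abundance_range(self, reaction_id)

    def pc_fva(self, objective_reaction: str, fractions=(0.0, 0.5, 0.9, 0.99), reactions=None):
        from .pc_analysis import pc_fva

        return pc_fva(self, objective_reaction, fractions=fractions, reactions=reactions)


def _optimize_sum(model: cobra.Model, reaction_ids: Sequence[str]) -> tuple[float, float]:
    present = [r for r in reaction_ids if r in model.reactions]
    if not present:
        return (0.0, 0.0)
    out = []
    for direction in ("min", "max"):
        with model:
            model.objective = {model.reactions.get_by_id(r): 1.0 for r in present}
            model.objective_direction = direction
            sol = model.optimize(raise_error=False)
            if sol.status != "optimal":
                raise RuntimeError(f"abundance optimization {direction} failed: {sol.status}")
            out.append(float(sol.objective_value))
    return tuple(out)  # type: ignore[return-value]


def build_context_model(
    pc_model: PCModel,
    fit: FitResult,
    s: float | None = None,
    budget: BudgetConfig | None = None,
) -> ContextModel:
    """Derive the slack-relaxed context-specific model from a fit.

    With ``s = 0`` measured proteins are pinned to p' exactly,
    unmeasured proteins to zero, and the relaxation budget is empty.
    """
    budget = (budget or pc_model.budget).fitting_mode()
    if s is None:
        s = budget.slack
    if s < 0 or s > 1:
        raise ValueError(f"slack must lie in [0, 1], got {s}")

    model = pc_model.model.copy()
    masses = {g: pc_model.proteins[g].molar_mass for g in pc_model.proteins}
    p_r_ub = s * float(sum(fit.p_prime[g] * masses[g] for g in fit.p_prime.index))

    model.reactions.get_by_id(PREFIX["pool_hb"]).bounds = (budget.p_hb_lb, budget.p_hb_ub)
    model.reactions.get_by_id(PREFIX["pool_la"]).bounds = (budget.p_la_lb, budget.p_la_ub)

    pool_total = model.metabolites.get_by_id(PREFIX["pool_met"] + "total")
    pool_r = cobra.Metabolite(PREFIX["pool_met"] + "r", compartment="pc")
    model.add_metabolites([pool_r])
    relax_pool = cobra.Reaction(PREFIX["pool_relax"])
    model.add_reactions([relax_pool])
    relax_pool.add_metabolites({pool_total: -1.0, pool_r: 1.0})
    relax_pool.bounds = (0.0, p_r_ub)

    relax_rxns = []
    for gene, rec in pc_model.proteins.items():
        dil = model.reactions.get_by_id(pc_model.dilution_id(gene))
        prot_met = model.metabolites.get_by_id(PREFIX["protein_met"] + gene)
        relax_cap = s * p_r_ub / rec.molar_mass
        p_prime = float(fit.p_prime.get(gene, 0.0))
        measured = not pd.isna(fit.p_data.get(gene, np.nan))
        if measured:
            dil.bounds = ((1.0 - s) * p_prime, p_prime)
        else:
            dil.bounds = (0.0, 0.0)
        rl = cobra.Reaction(pc_model.relax_id(gene))
        relax_rxns.append((rl, {pool_r: -rec.molar_mass, prot_met: 1.0}, (0.0, relax_cap)))
    model.add_reactions([r for r, _, _ in relax_rxns])
    for rl, stoich, bounds in relax_rxns:
        rl.add_metabolites(stoich)
        rl.bounds = bounds
    return ContextModel(model, pc_model, fit, s, p_r_ub)


# ---------------------------------------------------------------------------
# Slack calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    """Chosen slack and the diagnostic sweep table."""

    slack: float
    table: pd.DataFrame
    plateau_objectives: list[float]


def calibrate_slack(
    pc_model: PCModel,
    fits: Sequence[FitResult],
    objective_reaction: str,
    s_grid: Sequence[float] = (0.0, 0.01, 0.02, 0.03, 0.05, 0.1),
    plateau_fraction: float = 0.99,
) -> CalibrationResult:
    """Pick the smallest slack whose objective reaches the plateau.

    For every slack value and calibration fit (typically mean/median
    samples) the context model is solved lexicographically: maximize
    the objective reaction flux, then minimize the utilized relaxation
    budget at that optimum.  The chosen slack is the smallest grid
    value at which every calibration model attains at least
    ``plateau_fraction`` of its objective at the largest slack.
    """
    s_grid = sorted(s_grid)
    if len(s_grid) < 2:
        raise ValueError("s_grid needs at least two values")
    rows = []
    objectives = np.zeros((len(s_grid), len(fits)))
    for i, s in enumerate(s_grid):
        for m, fit in enumerate(fits):
            ctx = build_context_model(pc_model, fit, s=s)
            obj, relax_used = _lexicographic(ctx, objective_reaction)
            objectives[i, m] = obj
            rows.append({"s": s, "fit": m, "objective": obj, "relaxation_used": relax_used})
    table = pd.DataFrame(rows)
    plateau = objectives[-1, :]
    if np.all(np.abs(plateau) <= 1e-12):
        warnings.warn("objective is zero at every slack value; returning the largest slack")
        return CalibrationResult(s_grid[-1], table, list(plateau))
    for i, s in enumerate(s_grid):
        if np.all(objectives[i, :] >= plateau_fraction * plateau - 1e-12):
            return CalibrationResult(s, table, list(plateau))
    return CalibrationResult(s_grid[-1], table, list(plateau))


def _lexicographic(ctx: ContextModel, objective_reaction: str) -> tuple[float, float]:
    model = ctx.model
    with model:
        model.objective = model.reactions.get_by_id(objective_reaction)
        model.objective_direction = "max"
        sol = model.optimize(raise_error=False)
        if sol.status != "optimal":
            return float("nan"), float("nan")
        opt = float(sol.objective_value)
        rxn = model.reactions.get_by_id(objective_reaction)
        rxn.lower_bound = opt - 1e-9 * max(1.0, abs(opt))
        if PREFIX["pool_relax"] in model.reactions:
            model.objective = model.reactions.get_by_id(PREFIX["pool_relax"])
            model.objective_direction = "min"
            sol2 = model.optimize(raise_error=False)
            relax_used = float(sol2.objective_value) if sol2.status == "optimal" else float("nan")
        else:
            relax_used = 0.0
    return opt, relax_used
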