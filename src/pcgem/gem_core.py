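"""Genome-scale metabolic model handling and linear-programming machinery.

This module is the foundation everything else builds on: reading and
writing models (SBML or flat TSV tables), the stoichiometric matrix,
flux balance analysis (FBA), flux variability analysis (FVA), blocked
reaction detection, and elemental mass/charge balance checks.

Models are represented as :class:`cobra.Model` objects throughout the
package; COBRApy also supplies the underlying LP solver (GLPK via
optlang).  The conventions used here follow common COBRA practice:
fluxes in mmol/gDW/hr, "infinite" bounds encoded as +/-1000, and
pseudo-reactions (exchanges, demands, sinks, pooling reactions)
excluded from balance checking and connectivity.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import cobra
import numpy as np
import pandas as pd
from cobra.flux_analysis import find_blocked_reactions as _cobra_blocked
from cobra.flux_analysis import flux_variability_analysis as _cobra_fva
from scipy import sparse

__all__ = [
    "DEFAULT_BOUND",
    "FluxSolution",
    "FVARange",
    "read_model",
    "write_model",
    "read_tables",
    "write_tables",
    "stoichiometric_matrix",
    "base_metabolite_id",
    "is_pseudo_reaction",
    "pseudo_reaction_ids",
    "fba",
    "fva",
    "find_blocked",
    "balance_report",
    "balance_summary",
]

#: Default sentinel for an unbounded flux, mmol/gDW/hr (COBRA convention).
DEFAULT_BOUND = 1000.0

#: Identifier prefixes conventionally marking pseudo-reactions.
PSEUDO_PREFIXES = ("EX_", "DM_", "SK_", "POOL_", "PCPOOL_")


class ModelValidationError(ValueError):
    """A model failed structural validation (duplicate ids, bad GPR...)."""


@dataclass
class FluxSolution:
    """Outcome of one flux balance optimization.

    Attributes
    ----------
    fluxes : pandas.Series
        Optimal flux per reaction id (empty if not optimal).
    objective_value : float
        Optimal objective, NaN when the problem is not optimal.
    status : str
        One of ``optimal``, ``infeasible``, ``unbounded`` (or a raw
        solver status for anything more exotic).
    """

    fluxes: pd.Series
    objective_value: float
    status: str

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class FVARange:
    """Per-reaction flux range from variability analysis."""

    reaction_id: str
    minimum: float
    maximum: float


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_model(source: str | Path, infinite_bound: float = DEFAULT_BOUND) -> cobra.Model:
    """Read a model from an SBML file or a directory of flat TSV tables.

    Bounds of +/-inf are clamped to ``+/-infinite_bound``.  Duplicate
    identifiers raise :class:`ModelValidationError`.
    """
    source = Path(source)
    if source.is_dir():
        model = read_tables(source)
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = cobra.io.read_sbml_model(str(source))
        except Exception as exc:  # libsbml raises various error types
            raise ModelValidationError(f"could not parse SBML file {source}: {exc}") from exc
    _validate(model)
    for rxn in model.reactions:
        lb = max(rxn.lower_bound, -infinite_bound) if np.isfinite(rxn.lower_bound) else -infinite_bound
        ub = min(rxn.upper_bound, infinite_bound) if np.isfinite(rxn.upper_bound) else infinite_bound
        rxn.bounds = (lb, ub)
    return model


def write_model(model: cobra.Model, path: str | Path) -> None:
    """Write a model as SBML Level 3 (fbc bounds and GPRs included)."""
    cobra.io.write_sbml_model(model, str(path))


_TABLE_NAMES = ("metabolites.tsv", "reactions.tsv")


def read_tables(directory: str | Path) -> cobra.Model:
    """Read a model from ``metabolites.tsv`` + ``reactions.tsv``.

    The reaction table encodes stoichiometry as an equation string
    (``a_c + b_c --> c_c``) with columns
    ``id, name, equation, lower_bound, upper_bound, gpr, subsystem``;
    the metabolite table has ``id, name, formula, charge, compartment``.
    """
    directory = Path(directory)
    mets = pd.read_csv(directory / "metabolites.tsv", sep="\t", dtype=str).fillna("")
    rxns = pd.read_csv(directory / "reactions.tsv", sep="\t", dtype=str).fillna("")
    model = cobra.Model(directory.name or "model")
    metabolites = []
    for _, row in mets.iterrows():
        met = cobra.Metabolite(
            row["id"],
            name=row.get("name", ""),
            formula=row.get("formula", "") or None,
            compartment=row.get("compartment", "") or None,
        )
        if row.get("charge", "") != "":
            met.charge = int(float(row["charge"]))
        metabolites.append(met)
    model.add_metabolites(metabolites)
    for _, row in rxns.iterrows():
        rxn = cobra.Reaction(row["id"], name=row.get("name", ""))
        model.add_reactions([rxn])
        rxn.build_reaction_from_string(row["equation"])
        rxn.bounds = (float(row["lower_bound"]), float(row["upper_bound"]))
        if row.get("gpr", ""):
            rxn.gene_reaction_rule = row["gpr"]
        if row.get("subsystem", ""):
            rxn.subsystem = row["subsystem"]
    return model


def write_tables(model: cobra.Model, directory: str | Path) -> None:
    """Write the flat-table dialect read by :func:`read_tables`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mets = pd.DataFrame(
        {
            "id": [m.id for m in model.metabolites],
            "name": [m.name for m in model.metabolites],
            "formula": [m.formula or "" for m in model.metabolites],
            "charge": [m.charge if m.charge is not None else "" for m in model.metabolites],
            "compartment": [m.compartment or "" for m in model.metabolites],
        }
    )
    rxns = pd.DataFrame(
        {
            "id": [r.id for r in model.reactions],
            "name": [r.name for r in model.reactions],
            "equation": [r.build_reaction_string() for r in model.reactions],
            "lower_bound": [r.lower_bound for r in model.reactions],
            "upper_bound": [r.upper_bound for r in model.reactions],
            "gpr": [r.gene_reaction_rule for r in model.reactions],
            "subsystem": [r.subsystem or "" for r in model.reactions],
        }
    )
    mets.to_csv(directory / "metabolites.tsv", sep="\t", index=False)
    rxns.to_csv(directory / "reactions.tsv", sep="\t", index=False)


def _validate(model: cobra.Model) -> None:
    for attr in ("metabolites", "reactions", "genes"):
        ids = [obj.id for obj in getattr(model, attr)]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ModelValidationError(f"duplicate {attr} ids: {dupes}")


# ---------------------------------------------------------------------------
# Stoichiometry
# ---------------------------------------------------------------------------

def base_metabolite_id(met: cobra.Metabolite) -> str:
    """Strip the trailing ``_<compartment>`` tag from a metabolite id."""
    comp = met.compartment
    if comp and met.id.endswith(f"_{comp}"):
        return met.id[: -(len(comp) + 1)]
    return met.id


def stoichiometric_matrix(
    model: cobra.Model, merge_compartments: bool = False
) -> tuple[sparse.csr_matrix, list[str], list[str]]:
    """Stoichiometric matrix S with row/column identifier lists.

    Entry (i, j) is the coefficient of metabolite i in reaction j.
    With ``merge_compartments`` rows sharing a base id are summed, so a
    pure transport column becomes all-zero.
    """
    if merge_compartments:
        row_ids: list[str] = []
        index: dict[str, int] = {}
        for met in model.metabolites:
            base = base_metabolite_id(met)
            if base not in index:
                index[base] = len(row_ids)
                row_ids.append(base)
        row_of = {met.id: index[base_metabolite_id(met)] for met in model.metabolites}
    else:
        row_ids = [m.id for m in model.metabolites]
        row_of = {mid: i for i, mid in enumerate(row_ids)}
    col_ids = [r.id for r in model.reactions]
    mat = sparse.lil_matrix((len(row_ids), len(col_ids)))
    for j, rxn in enumerate(model.reactions):
        for met, coeff in rxn.metabolites.items():
            mat[row_of[met.id], j] += coeff
    return mat.tocsr(), row_ids, col_ids


def is_pseudo_reaction(reaction: cobra.Reaction) -> bool:
    """Whether a reaction is a boundary/demand/sink/pooling pseudo-reaction."""
    if reaction.boundary:
        return True
    if reaction.id.startswith(PSEUDO_PREFIXES):
        return True
    if not reaction.reactants or not reaction.products:
        return True
    return False


def pseudo_reaction_ids(model: cobra.Model) -> set[str]:
    return {r.id for r in model.reactions if is_pseudo_reaction(r)}


# ---------------------------------------------------------------------------
# FBA / FVA
# ---------------------------------------------------------------------------

def fba(
    model: cobra.Model,
    objective: str | None = None,
    sense: str = "max",
) -> FluxSolution:
    """Flux balance analysis: optimize ``objective`` subject to S v = 0.

    Infeasible or unbounded problems are surfaced in the returned
    status, never silently zeroed.
    """
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    with model:
        if objective is not None:
            model.objective = model.reactions.get_by_id(objective)
        model.objective_direction = "max" if sense == "max" else "min"
        sol = model.optimize(raise_error=False)
        status = sol.status
        if status != "optimal":
            return FluxSolution(pd.Series(dtype=float), float("nan"), status)
        return FluxSolution(sol.fluxes.copy(), float(sol.objective_value), "optimal")


def fva(
    model: cobra.Model,
    fraction_of_optimum: float = 0.0,
    reactions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Flux variability analysis at a given objective fraction.

    Returns a DataFrame indexed by reaction id with ``minimum`` and
    ``maximum`` columns.  With ``fraction_of_optimum`` > 0 the current
    objective is first optimized and constrained to at least that
    fraction of its optimum.
    """
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must lie in [0, 1]")
    reaction_list = None
    if reactions is not None:
        reaction_list = [model.reactions.get_by_id(r) for r in reactions]
    return _cobra_fva(
        model,
        reaction_list=reaction_list,
        fraction_of_optimum=fraction_of_optimum,
        processes=1,
    )


def find_blocked(model: cobra.Model, tolerance: float = 1e-6) -> set[str]:
    """Reactions whose FVA range at objective fraction 0 is within +/-tolerance of 0."""
    return set(_cobra_blocked(model, zero_cutoff=tolerance, processes=1))


# ---------------------------------------------------------------------------
# Mass / charge balance
# ---------------------------------------------------------------------------

#: Inert pseudo-element used for generic R-groups in pooled species.
R_GROUP = "R"


def _reaction_residuals(reaction: cobra.Reaction) -> tuple[dict[str, float] | None, float | None]:
    """Element and charge residuals of a reaction (None = uncheckable)."""
    elements: dict[str, float] = {}
    charge = 0.0
    charge_ok = True
    for met, coeff in reaction.metabolites.items():
        if not met.formula:
            return None, None
        for element, count in met.elements.items():
            elements[element] = elements.get(element, 0.0) + coeff * count
        if met.charge is None:
            charge_ok = False
        else:
            charge += coeff * met.charge
    residuals = {e: v for e, v in elements.items() if abs(v) > 1e-9}
    return residuals, (charge if charge_ok else None)


def balance_report(model: cobra.Model) -> pd.DataFrame:
    """Per-reaction mass and charge balance status.

    Pseudo-reactions (exchanges, demands, sinks) are excluded outright;
    reactions whose only elemental residual is in the generic R-group
    pseudo-element are pooling reactions and marked ``pooling``
    (excluded from summary percentages).  Reactions with any metabolite
    lacking a formula are ``uncheckable``, not failed.
    """
    rows = []
    for rxn in model.reactions:
        if is_pseudo_reaction(rxn):
            rows.append((rxn.id, "pseudo", None, None, ""))
            continue
        if any(not met.formula for met in rxn.metabolites):
            rows.append((rxn.id, "uncheckable", None, None, "missing formula"))
            continue
        residuals, charge = _reaction_residuals(rxn)
        non_r = {e: v for e, v in residuals.items() if e != R_GROUP}
        if residuals and not non_r:
            rows.append((rxn.id, "pooling", None, None, _fmt_res(residuals)))
            continue
        mass_ok = not non_r
        charge_ok = None if charge is None else abs(charge) <= 1e-9
        status = "balanced" if mass_ok and charge_ok in (True, None) else "unbalanced"
        rows.append((rxn.id, status, mass_ok, charge_ok, _fmt_res(residuals, charge)))
    return pd.DataFrame(
        rows, columns=["reaction_id", "status", "mass_ok", "charge_ok", "residuals"]
    ).set_index("reaction_id")


def _fmt_res(residuals: Mapping[str, float], charge: float | None = None) -> str:
    parts = [f"{e}:{v:+g}" for e, v in sorted(residuals.items())]
    if charge is not None and abs(charge) > 1e-9:
        parts.append(f"charge:{charge:+g}")
    return ";".join(parts)


def balance_summary(report: pd.DataFrame) -> dict[str, float]:
    """Percentage of checkable reactions that are mass / charge balanced."""
    checkable = report[report["mass_ok"].notna()]
    n = len(checkable)
    if n == 0:
        return {"n_checkable": 0, "mass_balanced_pct": float("nan"), "charge_balanced_pct": float("nan")}
    mass_pct = 100.0 * checkable["mass_ok"].sum() / n
    charged = checkable[checkable["charge_ok"].notna()]
    charge_pct = 100.0 * charged["charge_ok"].sum() / len(charged) if len(charged) else float("nan")
    return {
        "n_checkable": float(n),
        "mass_balanced_pct": float(mass_pct),
        "charge_balanced_pct": float(charge_pct),
    }
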