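"""Construction of proteome-constrained models.

A proteome-constrained model augments a genome-scale metabolic model
with explicit protein, complex and 'enzyme' entities:

* **proteins** ``p_j`` (nmol/gDW) enter through dilution reactions and
  draw mass ``p_j * w_j`` (mg/gDW) from a partitioned proteome budget
  (hemoglobin pool vs low-abundance pool, total capped at 1000 mg/gDW
  = 100% of cell dry weight);
* **complexes** ``x_l`` (nmol/gDW) assemble from protein subunits
  according to an integer stoichiometry ``C`` and may not exceed the
  available subunit abundance (``C x <= p``);
* **'enzyme' entities** ``e_i = e_i^fwd + e_i^rev`` unite all complexes
  able to catalyze reaction ``i``, each complex contributing its full
  abundance weighted by the rate-constant ratio ``r_l = k_l / k_avg``;
* **capacity coupling** limits flux by enzyme abundance,
  ``-k^rev e^rev <= v_i <= k^fwd e^fwd`` (with an explicit nmol->mmol
  conversion so fluxes stay in mmol/gDW/hr).

Complex-level rate constants are estimated from complex molar mass by
solvent-accessible-surface-area scaling, ``k_l = k_avg (M_l / mean M)^(3/4)``,
with reverse constants zeroed for irreversible reactions.

All added entities are encoded as pseudo-metabolites and
pseudo-reactions with fixed identifier prefixes, so a
:class:`PCModel` remains an ordinary (exportable) SBML model whose LP
is exactly the proteome-constrained problem.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import cobra
import numpy as np
import pandas as pd
from Bio.SeqUtils import molecular_weight as _bio_mw

from . import gem_core
from .gem_core import FluxSolution, fba

__all__ = [
    "AMINO_ACIDS",
    "NMOL_TO_MMOL",
    "PREFIX",
    "ProteinRecord",
    "ComplexRecord",
    "BudgetConfig",
    "Kinetics",
    "PCModel",
    "protein_molar_mass",
    "parse_gpr_complexes",
    "derive_complexes",
    "estimate_rate_constants",
    "build_pc_model",
    "read_protein_table",
    "write_protein_table",
    "read_complex_table",
    "write_complex_table",
    "write_pc_model",
    "read_pc_model",
]

#: The 20 standard amino acids (one-letter codes).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Conversion factor: protein amounts are carried in nmol/gDW while
#: fluxes are mmol/gDW/hr, so k*e capacity terms are scaled by 1e-6.
NMOL_TO_MMOL = 1e-6

#: Identifier prefixes for the pseudo-objects added to the base model.
PREFIX = {
    "protein_met": "prot_",
    "protein_dilution": "PROTDL_",
    "protein_sink": "PROTSK_",
    "protein_relax": "PROTRL_",
    "complex_formation": "CPLXFM_",
    "enzyme_met": "enz_",
    "enzyme_fwd": "ENZFM_",
    "enzyme_rev": "ENZRM_",
    "cap_fwd_met": "enzcapf_",
    "cap_rev_met": "enzcapr_",
    "cap_fwd_slack": "ENZSKF_",
    "cap_rev_slack": "ENZSKR_",
    "pool_met": "pcpool_",
    "pool_total": "PCPOOL_TOTAL",
    "pool_hb": "PCPOOL_HB",
    "pool_la": "PCPOOL_LA",
    "pool_relax": "PCPOOL_R",
}

#: SBML compartment holding every pseudo-species (all proteins are
#: treated as belonging to a single compartment).
PC_COMPARTMENT = "pc"


class PCBuildError(ValueError):
    """Inconsistent protein/complex inputs during model construction."""


# ---------------------------------------------------------------------------
# Protein and complex records
# ---------------------------------------------------------------------------

def protein_molar_mass(sequence: str) -> float:
    """Average-isotope molar mass of a protein, in mg/nmol.

    Residue masses are summed and one water added (standard peptide
    mass); 1 g/mol = 1e-6 mg/nmol.  Unknown letters raise a ValueError
    naming the offending position.
    """
    if not sequence:
        raise ValueError("empty protein sequence")
    for pos, letter in enumerate(sequence):
        if letter not in AMINO_ACIDS:
            raise ValueError(f"unknown amino acid {letter!r} at position {pos}")
    return _bio_mw(sequence, seq_type="protein") * 1e-6


@dataclass
class ProteinRecord:
    """One gene product: symbol, accession, molar mass, hemoglobin flag.

    ``molar_mass`` is in mg/nmol (= MDa); ``p_ub`` is the per-protein
    abundance upper bound in nmol/gDW (infinite means limited only by
    the proteome budget).
    """

    gene: str
    accession: str
    molar_mass: float
    is_hemoglobin: bool = False
    sequence: str | None = None
    p_ub: float = math.inf

    def __post_init__(self) -> None:
        if not self.molar_mass or self.molar_mass <= 0:
            raise ValueError(f"protein {self.gene}: molar mass must be positive")

    @classmethod
    def from_sequence(
        cls, gene: str, accession: str, sequence: str, is_hemoglobin: bool = False, p_ub: float = math.inf
    ) -> "ProteinRecord":
        return cls(gene, accession, protein_molar_mass(sequence), is_hemoglobin, sequence, p_ub)


@dataclass
class ComplexRecord:
    """A catalytic complex: subunit stoichiometry and catalyzed reactions.

    ``subunits`` maps gene symbol to positive integer copy number (one
    column of the complex stoichiometry matrix C); ``catalyzed`` lists
    ``(reaction_id, direction)`` pairs with direction in
    ``{"fwd", "rev", "both"}``.
    """

    complex_id: str
    subunits: dict[str, int]
    catalyzed: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for gene, copies in self.subunits.items():
            if copies <= 0 or int(copies) != copies:
                raise ValueError(f"complex {self.complex_id}: copy number for {gene} must be a positive integer")
        for _, direction in self.catalyzed:
            if direction not in ("fwd", "rev", "both"):
                raise ValueError(f"complex {self.complex_id}: bad direction {direction!r}")

    def molar_mass(self, proteins: Mapping[str, ProteinRecord]) -> float:
        """Stoichiometry-weighted sum of subunit masses, mg/nmol."""
        try:
            return sum(copies * proteins[g].molar_mass for g, copies in self.subunits.items())
        except KeyError as exc:
            raise PCBuildError(f"complex {self.complex_id} references unknown protein {exc.args[0]}") from exc


# ---------------------------------------------------------------------------
# GPR -> complexes
# ---------------------------------------------------------------------------

def parse_gpr_complexes(gpr: str) -> list[frozenset[str]]:
    """Expand a boolean GPR rule into its OR-branches (isozyme complexes).

    Each OR-branch becomes the gene set of one candidate complex
    (AND-conjuncts are subunits).  An empty rule yields no complexes
    (a spontaneous reaction).
    """
    gpr = (gpr or "").strip()
    if not gpr:
        return []
    tree = cobra.core.gene.GPR.from_string(gpr)
    if tree.body is None:
        return []
    return _expand(tree.body)


def _expand(node) -> list[frozenset[str]]:
    import ast

    if isinstance(node, ast.Name):
        return [frozenset([node.id])]
    if isinstance(node, ast.BoolOp):
        branches = [_expand(v) for v in node.values]
        if isinstance(node.op, ast.Or):
            out: list[frozenset[str]] = []
            for b in branches:
                out.extend(b)
            return out
        # AND: cartesian union of gene sets
        combos = [frozenset()]
        for b in branches:
            combos = [c | alt for c in combos for alt in b]
        return combos
    if isinstance(node, ast.Expression):
        return _expand(node.body)
    raise ValueError(f"unsupported GPR node: {ast.dump(node)}")


def derive_complexes(
    reaction_id: str,
    gpr: str,
    curated: Sequence[ComplexRecord] | None = None,
    direction: str = "both",
) -> list[ComplexRecord]:
    """Complexes for one reaction: curated records override derived ones.

    Derived complexes take copy number 1 per AND-subunit; curated
    records for the same reaction replace the derivation entirely.
    """
    if curated:
        matches = [c for c in curated if any(r == reaction_id for r, _ in c.catalyzed)]
        if matches:
            return list(matches)
    out = []
    seen: set[frozenset[str]] = set()
    for genes in parse_gpr_complexes(gpr):
        if genes in seen:
            continue
        seen.add(genes)
        cid = f"CPLX_{reaction_id}_{'_'.join(sorted(genes))}"
        out.append(ComplexRecord(cid, {g: 1 for g in sorted(genes)}, [(reaction_id, direction)]))
    return out


# ---------------------------------------------------------------------------
# Budgets and kinetics
# ---------------------------------------------------------------------------

@dataclass
class BudgetConfig:
    """Proteome budget partition and kinetic defaults.

    All masses in mg/gDW.  The hemoglobin pool carries at least 90% of
    a 1000 mg/gDW total budget, the low-abundance pool at most 10%.
    During proteome fitting the upper bounds tighten to 950/50 so the
    budget-scaled data sit exactly at the pool caps.  ``k_avg`` is the
    average effective rate constant, 65 1/s = 2.34e5 1/hr; ``slack``
    is the default relaxation fraction for context-specific models.
    """

    p_total_ub: float = 1000.0
    p_hb_lb: float = 900.0
    p_hb_ub: float = 1000.0
    p_la_lb: float = 0.0
    p_la_ub: float = 100.0
    k_avg: float = 2.34e5
    slack: float = 0.03
    sasa_exponent: float = 0.75

    def __post_init__(self) -> None:
        for lb, ub, name in (
            (0.0, self.p_total_ub, "total"),
            (self.p_hb_lb, self.p_hb_ub, "hemoglobin"),
            (self.p_la_lb, self.p_la_ub, "low-abundance"),
        ):
            if not 0 <= lb <= ub:
                raise ValueError(f"invalid {name} budget bounds [{lb}, {ub}]")

    def fitting_mode(self) -> "BudgetConfig":
        """Budget bounds used while fitting measured proteomes (950/50)."""
        return replace(self, p_hb_ub=950.0, p_la_ub=50.0)


@dataclass
class Kinetics:
    """Effective rate constants for every (reaction, complex) pairing.

    ``k_fwd``/``k_rev`` are enzyme-level constants (1/hr) per reaction;
    ``r_fwd``/``r_rev`` are the dimensionless complex-to-enzyme ratios
    ``k_l / k_avg`` keyed by (reaction_id, complex_id).
    """

    k_fwd: dict[str, float]
    k_rev: dict[str, float]
    r_fwd: dict[tuple[str, str], float]
    r_rev: dict[tuple[str, str], float]
    k_avg: float

    @property
    def n_nonzero(self) -> int:
        """Number of nonzero effective rate constants."""
        return sum(1 for v in self.r_fwd.values() if v > 0) + sum(
            1 for v in self.r_rev.values() if v > 0
        )


def estimate_rate_constants(
    complexes: Sequence[ComplexRecord],
    proteins: Mapping[str, ProteinRecord],
    reaction_bounds: Mapping[str, tuple[float, float]],
    k_avg: float = 2.34e5,
    sasa_exponent: float = 0.75,
) -> Kinetics:
    """Estimate effective rate constants from complex molar masses.

    Enzyme-level constants are uniform at ``k_avg``; complex-level
    constants scale with molar mass relative to the mean complex mass,
    ``k_l = k_avg (M_l / mean M)^sasa_exponent`` (solvent-accessible
    surface area scaling).  Reverse constants are zeroed whenever the
    catalyzed reaction is irreversible (``v_lb >= 0``).
    """
    if not complexes:
        raise ValueError("no complexes supplied")
    masses = {c.complex_id: c.molar_mass(proteins) for c in complexes}
    if any(m <= 0 for m in masses.values()):
        raise ValueError("nonpositive complex molar mass")
    mean_mass = float(np.mean(list(masses.values())))
    k_fwd: dict[str, float] = {}
    k_rev: dict[str, float] = {}
    r_fwd: dict[tuple[str, str], float] = {}
    r_rev: dict[tuple[str, str], float] = {}
    for cplx in complexes:
        k_l = k_avg * (masses[cplx.complex_id] / mean_mass) ** sasa_exponent
        ratio = k_l / k_avg
        for rxn_id, direction in cplx.catalyzed:
            if rxn_id not in reaction_bounds:
                raise PCBuildError(f"complex {cplx.complex_id} catalyzes unknown reaction {rxn_id}")
            lb, _ = reaction_bounds[rxn_id]
            reversible = lb < 0
            k_fwd[rxn_id] = k_avg
            k_rev[rxn_id] = k_avg if reversible else 0.0
            key = (rxn_id, cplx.complex_id)
            r_fwd[key] = ratio if direction in ("fwd", "both") else 0.0
            r_rev[key] = ratio if (reversible and direction in ("rev", "both")) else 0.0
    return Kinetics(k_fwd, k_rev, r_fwd, r_rev, k_avg)


# ---------------------------------------------------------------------------
# PCModel
# ---------------------------------------------------------------------------

class PCModel:
    """A proteome-constrained model: base GEM + protein/complex/enzyme layer.

    The augmented :attr:`model` is an ordinary COBRA model whose extra
    pseudo-reactions carry the proteome variables:

    ========================  =====================================
    flux of                   equals
    ========================  =====================================
    ``PROTDL_<gene>``         protein abundance p_j (nmol/gDW)
    ``CPLXFM_<complex>``      complex abundance x_l (nmol/gDW)
    ``ENZFM_/ENZRM_<rxn>``    enzyme entity e^fwd / e^rev (nmol/gDW)
    ``PCPOOL_HB/LA/TOTAL``    proteome budget masses (mg/gDW)
    ========================  =====================================

    Use :meth:`fit` to fit a measured proteome (quadratic program) and
    :func:`pcgem.proteome_fit.build_context_model` to derive a
    context-specific model from the result.
    """

    def __init__(
        self,
        model: cobra.Model,
        base_model: cobra.Model,
        proteins: Mapping[str, ProteinRecord],
        complexes: Sequence[ComplexRecord],
        kinetics: Kinetics,
        budget: BudgetConfig,
    ) -> None:
        self.model = model
        self.base_model = base_model
        self.proteins = dict(proteins)
        self.complexes = list(complexes)
        self.kinetics = kinetics
        self.budget = budget

    # -- identifier helpers -------------------------------------------------
    def dilution_id(self, gene: str) -> str:
        return PREFIX["protein_dilution"] + gene

    def relax_id(self, gene: str) -> str:
        return PREFIX["protein_relax"] + gene

    def complex_id(self, complex_id: str) -> str:
        return PREFIX["complex_formation"] + complex_id

    def enzyme_fwd_id(self, reaction_id: str) -> str:
        return PREFIX["enzyme_fwd"] + reaction_id

    def enzyme_rev_id(self, reaction_id: str) -> str:
        return PREFIX["enzyme_rev"] + reaction_id

    @property
    def enzymatic_reactions(self) -> list[str]:
        """Base reactions coupled to an enzyme entity."""
        return sorted({r for r, _ in self.kinetics.r_fwd})

    @property
    def accession_to_gene(self) -> dict[str, str]:
        return {p.accession: p.gene for p in self.proteins.values()}

    @property
    def hb_genes(self) -> set[str]:
        return {g for g, p in self.proteins.items() if p.is_hemoglobin}

    def base_reaction_ids(self) -> list[str]:
        return [r.id for r in self.base_model.reactions]

    # -- modeling surface ---------------------------------------------------
    def optimize(self, objective: str | None = None, sense: str = "max") -> FluxSolution:
        """Proteome-constrained FBA."""
        return fba(self.model, objective=objective, sense=sense)

    def protein_abundances(self, solution: FluxSolution) -> pd.Series:
        """Extract the protein abundance vector p (nmol/gDW) from a solution."""
        return pd.Series(
            {g: solution.fluxes.get(self.dilution_id(g), 0.0) for g in self.proteins},
            name="p",
        )

    def fit(self, p_data: pd.Series, budget: BudgetConfig | None = None, **solver_options):
        """Fit a measured proteome by quadratic programming.

        Thin wrapper over :func:`pcgem.proteome_fit.fit_proteome`;
        returns a :class:`pcgem.proteome_fit.FitResult`.
        """
        from .proteome_fit import fit_proteome

        return fit_proteome(self, p_data, budget=budget, **solver_options)

    def copy(self) -> "PCModel":
        return PCModel(
            self.model.copy(),
            self.base_model,
            dict(self.proteins),
            list(self.complexes),
            self.kinetics,
            self.budget,
        )

    def construction_summary(self) -> dict[str, int]:
        return {
            "n_proteins": len(self.proteins),
            "n_complexes": len(self.complexes),
            "n_enzyme_entities": len(self.enzymatic_reactions),
            "n_nonzero_rate_constants": self.kinetics.n_nonzero,
        }


def build_pc_model(
    model: cobra.Model,
    proteins: Iterable[ProteinRecord],
    complexes: Sequence[ComplexRecord],
    kinetics: Kinetics | None = None,
    budget: BudgetConfig | None = None,
) -> PCModel:
    """Assemble a :class:`PCModel` from a GEM and protein/complex tables.

    Every gene referenced by a complex must have a protein record; the
    input model is copied, never mutated.
    """
    budget = budget or BudgetConfig()
    prot_map = {p.gene: p for p in proteins}
    for cplx in complexes:
        for gene in cplx.subunits:
            if gene not in prot_map:
                raise PCBuildError(f"complex {cplx.complex_id} references protein {gene} with no record")
    if kinetics is None:
        bounds = {r.id: (r.lower_bound, r.upper_bound) for r in model.reactions}
        kinetics = estimate_rate_constants(
            complexes, prot_map, bounds, k_avg=budget.k_avg, sasa_exponent=budget.sasa_exponent
        )

    base = model
    aug = model.copy()
    P = PREFIX

    def met(mid: str) -> cobra.Metabolite:
        m = cobra.Metabolite(mid, compartment=PC_COMPARTMENT)
        aug.add_metabolites([m])
        return m

    pool_total = met(P["pool_met"] + "total")
    pool_hb = met(P["pool_met"] + "hb")
    pool_la = met(P["pool_met"] + "la")

    rxn_total = cobra.Reaction(P["pool_total"])
    rxn_hb = cobra.Reaction(P["pool_hb"])
    rxn_la = cobra.Reaction(P["pool_la"])
    aug.add_reactions([rxn_total, rxn_hb, rxn_la])
    rxn_total.add_metabolites({pool_total: 1.0})
    rxn_total.bounds = (0.0, budget.p_total_ub)
    rxn_hb.add_metabolites({pool_total: -1.0, pool_hb: 1.0})
    rxn_hb.bounds = (budget.p_hb_lb, budget.p_hb_ub)
    rxn_la.add_metabolites({pool_total: -1.0, pool_la: 1.0})
    rxn_la.bounds = (budget.p_la_lb, budget.p_la_ub)

    # proteins: dilution draws w_j mg from the group pool per nmol
    prot_mets: dict[str, cobra.Metabolite] = {}
    for gene, rec in prot_map.items():
        pm = met(P["protein_met"] + gene)
        prot_mets[gene] = pm
        pool = pool_hb if rec.is_hemoglobin else pool_la
        dil = cobra.Reaction(P["protein_dilution"] + gene)
        sink = cobra.Reaction(P["protein_sink"] + gene)
        aug.add_reactions([dil, sink])
        dil.add_metabolites({pool: -rec.molar_mass, pm: 1.0})
        ub = rec.p_ub
        if not math.isfinite(ub):
            ub = budget.p_total_ub / rec.molar_mass  # budget-implied cap
        dil.bounds = (0.0, ub)
        sink.add_metabolites({pm: -1.0})  # C x <= p slack
        sink.bounds = (0.0, budget.p_total_ub / rec.molar_mass)

    # enzyme pools per enzymatic reaction
    enz_rxns = sorted({r for (r, _) in kinetics.r_fwd})
    enz_mets = {r: met(P["enzyme_met"] + r) for r in enz_rxns}

    # complexes: consume subunits, supply r_l per catalyzed enzyme pool
    for cplx in complexes:
        form = cobra.Reaction(P["complex_formation"] + cplx.complex_id)
        aug.add_reactions([form])
        stoich: dict[cobra.Metabolite, float] = {
            prot_mets[g]: -float(copies) for g, copies in cplx.subunits.items()
        }
        for rxn_id, _ in cplx.catalyzed:
            key = (rxn_id, cplx.complex_id)
            supply = max(kinetics.r_fwd.get(key, 0.0), kinetics.r_rev.get(key, 0.0))
            if supply > 0:
                stoich[enz_mets[rxn_id]] = stoich.get(enz_mets[rxn_id], 0.0) + supply
        form.add_metabolites(stoich)
        max_x = budget.p_total_ub / cplx.molar_mass(prot_map)
        form.bounds = (0.0, max_x)

    # enzyme formation + capacity coupling
    for rxn_id in enz_rxns:
        target = aug.reactions.get_by_id(rxn_id)
        k_f = kinetics.k_fwd[rxn_id]
        k_r = kinetics.k_rev[rxn_id]
        e_cap = budget.p_total_ub / min(
            c.molar_mass(prot_map) for c in complexes if any(r == rxn_id for r, _ in c.catalyzed)
        )
        cap_f = met(P["cap_fwd_met"] + rxn_id)
        enz_f = cobra.Reaction(P["enzyme_fwd"] + rxn_id)
        slack_f = cobra.Reaction(P["cap_fwd_slack"] + rxn_id)
        aug.add_reactions([enz_f, slack_f])
        enz_f.add_metabolites({enz_mets[rxn_id]: -1.0, cap_f: k_f * NMOL_TO_MMOL})
        enz_f.bounds = (0.0, e_cap)
        slack_f.add_metabolites({cap_f: -1.0})
        slack_f.bounds = (0.0, np.inf)
        target.add_metabolites({cap_f: -1.0})
        if k_r > 0:
            cap_r = met(P["cap_rev_met"] + rxn_id)
            enz_r = cobra.Reaction(P["enzyme_rev"] + rxn_id)
            slack_r = cobra.Reaction(P["cap_rev_slack"] + rxn_id)
            aug.add_reactions([enz_r, slack_r])
            enz_r.add_metabolites({enz_mets[rxn_id]: -1.0, cap_r: k_r * NMOL_TO_MMOL})
            enz_r.bounds = (0.0, e_cap)
            slack_r.add_metabolites({cap_r: -1.0})
            slack_r.bounds = (0.0, np.inf)
            target.add_metabolites({cap_r: 1.0})

    return PCModel(aug, base, prot_map, complexes, kinetics, budget)


# ---------------------------------------------------------------------------
# Table and model I/O
# ---------------------------------------------------------------------------

def read_protein_table(path: str | Path) -> list[ProteinRecord]:
    """Read a protein TSV: gene, accession, sequence|molar_mass_da, is_hemoglobin."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = []
    for _, row in df.iterrows():
        hb = str(row.get("is_hemoglobin", "")).strip().lower() in ("1", "true", "yes")
        seq = row.get("sequence", "") or None
        if seq:
            rec = ProteinRecord.from_sequence(row["gene"], row["accession"], seq, hb)
        else:
            mass_da = float(row["molar_mass_da"])
            rec = ProteinRecord(row["gene"], row["accession"], mass_da * 1e-6, hb)
        records.append(rec)
    return records


def write_protein_table(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    rows = [
        {
            "gene": p.gene,
            "accession": p.accession,
            "sequence": p.sequence or "",
            "molar_mass_da": p.molar_mass * 1e6,
            "is_hemoglobin": int(p.is_hemoglobin),
        }
        for p in proteins
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_complex_table(path: str | Path) -> list[ComplexRecord]:
    """Read a complex TSV: complex_id, subunits "gene:copies;...", reaction_ids, direction."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = []
    for _, row in df.iterrows():
        subunits = {}
        for part in row["subunits"].split(";"):
            gene, _, copies = part.partition(":")
            subunits[gene.strip()] = int(copies or 1)
        direction = row.get("direction", "") or "both"
        catalyzed = [(r.strip(), direction) for r in row["reaction_ids"].split(";") if r.strip()]
        records.append(ComplexRecord(row["complex_id"], subunits, catalyzed))
    return records


def write_complex_table(complexes: Iterable[ComplexRecord], path: str | Path) -> None:
    rows = []
    for c in complexes:
        direction = c.catalyzed[0][1] if c.catalyzed else "both"
        rows.append(
            {
                "complex_id": c.complex_id,
                "subunits": ";".join(f"{g}:{n}" for g, n in c.subunits.items()),
                "reaction_ids": ";".join(r for r, _ in c.catalyzed),
                "direction": direction,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_pc_model(pcm: PCModel, sbml_path: str | Path, sidecar_path: str | Path | None = None) -> None:
    """Write the augmented model as SBML plus a JSON sidecar.

    The sidecar holds everything SBML cannot: protein records, complex
    tables, rate constants and the budget configuration, so the
    :class:`PCModel` can be reconstructed by :func:`read_pc_model`.
    """
    sbml_path = Path(sbml_path)
    if sidecar_path is None:
        sidecar_path = sbml_path.with_suffix(".json")
    cobra.io.write_sbml_model(pcm.model, str(sbml_path))
    payload = {
        "proteins": [
            {
                "gene": p.gene,
                "accession": p.accession,
                "molar_mass": p.molar_mass,
                "is_hemoglobin": p.is_hemoglobin,
                "sequence": p.sequence,
                "p_ub": None if math.isinf(p.p_ub) else p.p_ub,
            }
            for p in pcm.proteins.values()
        ],
        "complexes": [
            {"complex_id": c.complex_id, "subunits": c.subunits, "catalyzed": c.catalyzed}
            for c in pcm.complexes
        ],
        "kinetics": {
            "k_fwd": pcm.kinetics.k_fwd,
            "k_rev": pcm.kinetics.k_rev,
            "r_fwd": [[r, c, v] for (r, c), v in pcm.kinetics.r_fwd.items()],
            "r_rev": [[r, c, v] for (r, c), v in pcm.kinetics.r_rev.items()],
            "k_avg": pcm.kinetics.k_avg,
        },
        "budget": {
            k: getattr(pcm.budget, k)
            for k in (
                "p_total_ub", "p_hb_lb", "p_hb_ub", "p_la_lb", "p_la_ub",
                "k_avg", "slack", "sasa_exponent",
            )
        },
        "base_reactions": [r.id for r in pcm.base_model.reactions],
    }
    Path(sidecar_path).write_text(json.dumps(payload, indent=1))


def read_pc_model(sbml_path: str | Path, sidecar_path: str | Path | None = None) -> PCModel:
    """Reconstruct a :class:`PCModel` written by :func:`write_pc_model`."""
    sbml_path = Path(sbml_path)
    if sidecar_path is None:
        sidecar_path = sbml_path.with_suffix(".json")
    payload = json.loads(Path(sidecar_path).read_text())
    aug = gem_core.read_model(sbml_path, infinite_bound=np.inf)
    proteins = {
        d["gene"]: ProteinRecord(
            d["gene"], d["accession"], d["molar_mass"], d["is_hemoglobin"], d.get("sequence"),
            math.inf if d.get("p_ub") is None else d["p_ub"],
        )
        for d in payload["proteins"]
    }
    complexes = [
        ComplexRecord(d["complex_id"], {g: int(n) for g, n in d["subunits"].items()},
                      [(r, dr) for r, dr in d["catalyzed"]])
        for d in payload["complexes"]
    ]
    kin = payload["kinetics"]
    kinetics = Kinetics(
        dict(kin["k_fwd"]),
        dict(kin["k_rev"]),
        {(r, c): v for r, c, v in kin["r_fwd"]},
        {(r, c): v for r, c, v in kin["r_rev"]},
        kin["k_avg"],
    )
    budget = BudgetConfig(**payload["budget"])
    base_ids = set(payload["base_reactions"])
    base = aug.copy()
    base.remove_reactions([r for r in base.reactions if r.id not in base_ids], remove_orphans=True)
    # strip pc pseudo-species left on base reactions
    for rxn in base.reactions:
        drop = {m: -c for m, c in rxn.metabolites.items() if m.compartment == PC_COMPARTMENT}
        if drop:
            rxn.add_metabolites(drop)
    base.remove_metabolites([m for m in base.metabolites if m.compartment == PC_COMPARTMENT and not m.reactions])
    return PCModel(aug, base, proteins, complexes, kinetics, budget)
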