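"""Synthetic study generator: toy metabolic models, protein/complex
tables, and donor proteome panels with planted structure.

The generator emulates the statistical shape of a stored red blood
cell proteomics study: a hemoglobin-dominated proteome (~95% of
protein mass), log-normally distributed low-abundance proteins,
missing-at-random detection, three storage time points per donor, a
mild multiplicative storage drift, and metadata columns that are
monotone functions of chosen enzyme abundances.  A planted
"limiting" enzyme is given an abundance low enough that its catalytic
capacity binds the flux of its reaction, so the downstream
classification should recover it as abundance-dependent; the planted
truth is emitted alongside the data.

The toy metabolic model is a small, fully mass- and charge-balanced
network with a glucose-to-lactate backbone, a glycogen branch point,
an ATP-coupled sodium/potassium pump (the default objective), leak
and spontaneous reactions, and a fatty-acid branch whose precursor
has no producer — a structurally blocked pathway mirroring how the
absence of a carboxylase blocks lipid synthesis in mature red cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import cobra
import numpy as np
import pandas as pd

from .pc_build import ComplexRecord, ProteinRecord, derive_complexes, protein_molar_mass

__all__ = [
    "SyntheticSpec",
    "PlantedTruth",
    "OBJECTIVE_REACTION",
    "make_toy_gem",
    "make_protein_tables",
    "sample_donor_proteomes",
    "write_dataset",
]

#: Default objective reaction of the toy model (the Na+/K+-ATPase pump).
OBJECTIVE_REACTION = "NAKPUMP"


@dataclass
class SyntheticSpec:
    """Study-design parameters for the synthetic donor panel.

    ``planted_limiting`` pairs (gene, reaction) mark enzymes whose
    abundance is the binding constraint of their reaction;
    ``metadata_links`` maps a metadata column to (gene, sign) so the
    column is a monotone function of that enzyme's abundance.
    ``storage_drift`` is a per-gene multiplicative factor per storage
    day.  ``lognormal_sigma`` is the per-donor log-scale spread of
    low-abundance proteins.
    """

    n_donors: int = 50
    storage_days: tuple[int, ...] = (10, 23, 42)
    hb_mass_fraction: float = 0.95
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 0.35
    planted_sigma: float = 0.45
    missing_rate: float = 0.15
    storage_drift: dict[str, float] = field(
        default_factory=lambda: {"GYS1": 0.995}
    )
    planted_limiting: tuple[tuple[str, str], ...] = (
        ("ATP1A1", OBJECTIVE_REACTION),
    )
    metadata_links: dict[str, tuple[str, float]] = field(
        default_factory=lambda: {
            "hematocrit": ("ATP1A1", 1.0),
            "oxidative_hemolysis": ("GYS1", -1.0),
        }
    )
    metadata_noise: float = 0.25
    n_decoy_proteins: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0 < self.hb_mass_fraction < 1:
            raise ValueError("hb_mass_fraction must lie in (0, 1)")


@dataclass
class PlantedTruth:
    """Ground truth the analysis pipeline should recover."""

    dependent_reactions: list[str]
    metadata_signs: dict[str, tuple[str, float]]
    limiting_genes: list[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "dependent_reactions": self.dependent_reactions,
                "metadata_signs": {k: list(v) for k, v in self.metadata_signs.items()},
                "limiting_genes": self.limiting_genes,
            },
            indent=1,
        )


# ---------------------------------------------------------------------------
# Toy model
# ---------------------------------------------------------------------------

_METS = [
    # id, formula, charge, compartment
    ("glc_e", "C6H12O6", 0, "e"), ("glc_c", "C6H12O6", 0, "c"),
    ("g6p_c", "C6H11O9P", -2, "c"),
    ("lac_c", "C3H5O3", -1, "c"), ("lac_e", "C3H5O3", -1, "e"),
    ("atp_c", "C10H12N5O13P3", -4, "c"), ("adp_c", "C10H12N5O10P2", -3, "c"),
    ("pi_c", "HPO4", -2, "c"),
    ("h_c", "H", 1, "c"), ("h_e", "H", 1, "e"),
    ("h2o_c", "H2O", 0, "c"),
    ("na1_c", "Na", 1, "c"), ("na1_e", "Na", 1, "e"),
    ("k_c", "K", 1, "c"), ("k_e", "K", 1, "e"),
    ("glyg_c", "C6H12O6", 0, "c"),
    ("malcoa_c", "C3H4O3", 0, "c"),
    ("fa_c", "C6H8O6", 0, "c"),
    ("fael_c", "C9H12O9", 0, "c"),
]

_RXNS = [
    # id, equation, (lb, ub), gpr, subsystem
    ("EX_glc_e", "glc_e <=>", (-2.0, 1000.0), "", "Exchange"),
    ("EX_lac_e", "lac_e <=>", (0.0, 1000.0), "", "Exchange"),
    ("EX_h_e", "h_e <=>", (-1000.0, 1000.0), "", "Exchange"),
    ("GLCT", "glc_e --> glc_c", (0.0, 1000.0), "SLC2A1", "Transport"),
    ("HEX", "glc_c + atp_c --> g6p_c + adp_c + h_c", (0.0, 1000.0), "HK1", "Carbohydrate metabolism"),
    ("GLYCL", "g6p_c + 3 adp_c + 2 pi_c + h_c --> 2 lac_c + 3 atp_c + 2 h2o_c",
     (0.0, 1000.0), "PKLR or PKM", "Carbohydrate metabolism"),
    ("LACT", "lac_c + h_c <=> lac_e + h_e", (-1000.0, 1000.0), "SLC16A1", "Transport"),
    (OBJECTIVE_REACTION,
     "atp_c + h2o_c + na1_c + k_e --> adp_c + pi_c + h_c + na1_e + k_c",
     (0.0, 1000.0), "ATP1A1 and ATP1B1", "Transport"),
    ("NALEAK", "na1_e --> na1_c", (0.0, 1000.0), "", "Transport"),
    ("KLEAK", "k_c --> k_e", (0.0, 1000.0), "KCNN4", "Transport"),
    ("ATPM", "atp_c + h2o_c --> adp_c + pi_c + h_c", (0.0, 1000.0), "", "Other"),
    ("GLGS", "g6p_c + h2o_c --> glyg_c + pi_c", (0.0, 1000.0), "GYS1", "Carbohydrate metabolism"),
    ("DM_glyg_c", "glyg_c -->", (0.0, 1000.0), "", "Demand"),
    ("FAS", "2 malcoa_c --> fa_c", (0.0, 1000.0), "FASN", "Lipid metabolism"),
    ("FAEL", "fa_c + malcoa_c --> fael_c", (0.0, 1000.0), "ELOVL2", "Lipid metabolism"),
    ("DM_fael_c", "fael_c -->", (0.0, 1000.0), "", "Demand"),
]

#: Reactions forming the structurally blocked branch (no producer of
#: the malonyl-type precursor exists in the model).
BLOCKED_BRANCH = ("FAS", "FAEL", "DM_fael_c")


def make_toy_gem(seed: int = 0) -> cobra.Model:
    """Deterministic small metabolic model (20 reactions, 20 metabolites).

    The construction does not depend on the seed (it is accepted for
    interface symmetry); identical calls produce identical models.
    """
    model = cobra.Model("toy_rbc")
    mets = [
        cobra.Metabolite(mid, formula=formula, charge=charge, compartment=comp)
        for mid, formula, charge, comp in _METS
    ]
    model.add_metabolites(mets)
    for rid, equation, bounds, gpr, subsystem in _RXNS:
        rxn = cobra.Reaction(rid)
        model.add_reactions([rxn])
        rxn.build_reaction_from_string(equation)
        rxn.bounds = bounds
        if gpr:
            rxn.gene_reaction_rule = gpr
        rxn.subsystem = subsystem
    model.objective = OBJECTIVE_REACTION
    return model


# ---------------------------------------------------------------------------
# Protein and complex tables
# ---------------------------------------------------------------------------

_SEQ_LENGTHS = {
    "HBB_POOL": 141,  # hemoglobin pool protein
    "SLC2A1": 492, "HK1": 480, "PKLR": 450, "PKM": 440,
    "SLC16A1": 500, "ATP1A1": 1800, "ATP1B1": 180, "KCNN4": 427,
    "GYS1": 410, "FASN": 520, "ELOVL2": 296,
}

#: UniProtKB-style accessions for the toy genes (synthetic).
_ACCESSIONS = {g: f"SYN{i:05d}" for i, g in enumerate(sorted(_SEQ_LENGTHS), start=1)}


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    from .pc_build import AMINO_ACIDS

    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def make_protein_tables(
    model: cobra.Model, seed: int = 0
) -> tuple[list[ProteinRecord], list[ComplexRecord]]:
    """Protein and complex records for a toy model.

    Every GPR gene gets a protein record with a random (but
    seed-deterministic) sequence; one hemoglobin-flagged pool protein
    is added.  The sodium/potassium pump gets a curated hetero-dimeric
    complex with subunit copies {2, 2}; all other complexes are
    derived from the GPR rules (the isozyme OR rule yields two
    single-subunit complexes).
    """
    rng = np.random.default_rng(seed)
    proteins = []
    for gene in sorted(_SEQ_LENGTHS):
        seq = _random_sequence(rng, _SEQ_LENGTHS[gene])
        proteins.append(
            ProteinRecord.from_sequence(
                gene, _ACCESSIONS[gene], seq, is_hemoglobin=(gene == "HBB_POOL")
            )
        )
    model_genes = {g.id for g in model.genes}
    missing = model_genes - set(_SEQ_LENGTHS)
    if missing:
        raise ValueError(f"no sequence template for genes {sorted(missing)}")

    curated = [
        ComplexRecord(
            "CPLX_NAKPUMP_DIMER",
            {"ATP1A1": 2, "ATP1B1": 2},
            [(OBJECTIVE_REACTION, "fwd")],
        )
    ]
    complexes: list[ComplexRecord] = []
    for rxn in model.reactions:
        if not rxn.gene_reaction_rule:
            continue
        direction = "both" if rxn.lower_bound < 0 else "fwd"
        complexes.extend(
            derive_complexes(rxn.id, rxn.gene_reaction_rule, curated=curated, direction=direction)
        )
    return proteins, complexes


# ---------------------------------------------------------------------------
# Donor proteome panel
# ---------------------------------------------------------------------------

#: Baseline share of the low-abundance proteome mass given to each
#: planted limiting subunit; chosen so the pump's catalytic capacity
#: sits strictly below both the flux the metabolic network alone
#: would allow and the slack-relaxation floor of any co-essential
#: enzyme, making the planted enzyme the binding constraint.
_PLANTED_MASS_SHARE = 0.003


def sample_donor_proteomes(
    proteins: Sequence[ProteinRecord],
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Draw the raw abundance matrix, hemoglobin table, metadata, and truth.

    Returns ``(raw_matrix, hb_table, metadata, truth)`` where the raw
    matrix rows are accessions and columns are ``<donor>_<day>``
    sample ids.  Abundances are relative intensities (the total
    protein approach rescales them downstream); hemoglobin carries
    ``hb_mass_fraction`` of each sample's mass on average.  Entries
    are masked missing at random, never for hemoglobin or the planted
    limiting enzymes.
    """
    rng = np.random.default_rng(spec.seed)
    prot_map = {p.gene: p for p in proteins}
    hb_genes = [p.gene for p in proteins if p.is_hemoglobin]
    if not hb_genes:
        raise ValueError("need a hemoglobin-flagged protein")
    planted_genes = sorted({g for g, _ in spec.planted_limiting})
    la_genes = [p.gene for p in proteins if not p.is_hemoglobin]
    other_genes = [g for g in la_genes if g not in planted_genes]

    # baseline molar abundances from mass shares (arbitrary total mass 1)
    la_mass = 1.0 - spec.hb_mass_fraction
    base_mass: dict[str, float] = {}
    for g in planted_genes:
        base_mass[g] = _PLANTED_MASS_SHARE * la_mass
    share_left = max(1.0 - _PLANTED_MASS_SHARE * len(planted_genes), 0.0)
    for g in other_genes:
        base_mass[g] = share_left * la_mass / max(len(other_genes), 1)
    baseline = {g: base_mass[g] / prot_map[g].molar_mass for g in la_genes}

    decoys = [f"DEC{i:05d}" for i in range(1, spec.n_decoy_proteins + 1)]
    decoy_base = np.exp(rng.normal(spec.lognormal_mu, 1.0, size=len(decoys)))
    decoy_mass = 0.05 * la_mass  # decoys carry a sliver of unmapped mass
    if len(decoys):
        decoy_base *= decoy_mass / decoy_base.sum()

    donors = [f"D{i:03d}" for i in range(1, spec.n_donors + 1)]
    hb_conc = rng.normal(13.5, 1.0, size=len(donors)).clip(9.0, 18.0)
    hb_table = pd.DataFrame({"donor_id": donors, "hb_concentration": hb_conc})

    accessions = [prot_map[g].accession for g in hb_genes + la_genes] + decoys
    gene_of_acc = {prot_map[g].accession: g for g in hb_genes + la_genes}
    columns: dict[str, np.ndarray] = {}
    meta_rows: dict[str, dict[str, float]] = {}
    log_abund: dict[tuple[str, str], float] = {}  # (donor, gene) -> log donor effect

    for donor in donors:
        donor_effect = {}
        for g in la_genes:
            sigma = spec.planted_sigma if g in planted_genes else spec.lognormal_sigma
            donor_effect[g] = rng.normal(0.0, sigma)
        decoy_effect = rng.normal(0.0, spec.lognormal_sigma, size=len(decoys))
        donor_hb_fraction = spec.hb_mass_fraction + rng.normal(0.0, 0.003)
        for day in spec.storage_days:
            values = {}
            la_total_mass = 0.0
            for g in la_genes:
                drift = spec.storage_drift.get(g, 1.0) ** day
                v = baseline[g] * np.exp(donor_effect[g]) * drift
                values[prot_map[g].accession] = v
                la_total_mass += v * prot_map[g].molar_mass
            for acc, base, eff in zip(decoys, decoy_base, decoy_effect):
                values[acc] = base * np.exp(eff)
            # hemoglobin set so its mass share is ~hb_mass_fraction
            f = float(np.clip(donor_hb_fraction, 0.01, 0.99))
            hb_total = la_total_mass * f / (1.0 - f)
            for g in hb_genes:
                values[prot_map[g].accession] = hb_total / len(hb_genes) / prot_map[g].molar_mass
            col = np.array([values[a] for a in accessions])
            # missing-at-random mask; protected: hemoglobin + planted
            protected = {prot_map[g].accession for g in hb_genes + planted_genes}
            mask = rng.random(len(accessions)) < spec.missing_rate
            for idx, acc in enumerate(accessions):
                if acc in protected:
                    mask[idx] = False
            col = col.astype(float)
            col[mask] = np.nan
            columns[f"{donor}_{day}"] = col
        for g in la_genes:
            log_abund[(donor, g)] = donor_effect[g]
        # metadata per donor from linked enzyme abundances
        row = {}
        for col_name, (gene, sign) in spec.metadata_links.items():
            noise = rng.normal(0.0, spec.metadata_noise)
            row[col_name] = sign * donor_effect.get(gene, 0.0) + noise
        row["donor_age"] = float(rng.integers(18, 70))
        meta_rows[donor] = row

    raw = pd.DataFrame(columns, index=accessions)
    metadata = pd.DataFrame(
        {
            f"{donor}_{day}": meta_rows[donor]
            for donor in donors
            for day in spec.storage_days
        }
    ).T
    truth = PlantedTruth(
        dependent_reactions=sorted({r for _, r in spec.planted_limiting}),
        metadata_signs=dict(spec.metadata_links),
        limiting_genes=planted_genes,
    )
    return raw, hb_table, metadata, truth


def write_dataset(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate the full synthetic study and write every file dialect.

    Emits the toy model (SBML + flat tables), protein/complex TSVs,
    the abundance CSV, hemoglobin CSV, metadata CSV and truth JSON.
    """
    from . import gem_core
    from .pc_build import write_complex_table, write_protein_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = make_toy_gem(spec.seed)
    proteins, complexes = make_protein_tables(model, spec.seed)
    raw, hb, metadata, truth = sample_donor_proteomes(proteins, spec)
    paths = {
        "model": out / "toy_gem.xml",
        "proteins": out / "proteins.tsv",
        "complexes": out / "complexes.tsv",
        "abundance": out / "abundance.csv",
        "hb": out / "hb.csv",
        "metadata": out / "metadata.csv",
        "truth": out / "truth.json",
    }
    gem_core.write_model(model, paths["model"])
    write_protein_table(proteins, paths["proteins"])
    write_complex_table(complexes, paths["complexes"])
    raw.to_csv(paths["abundance"])
    hb.to_csv(paths["hb"], index=False)
    metadata.to_csv(paths["metadata"])
    paths["truth"].write_text(truth.to_json())
    return paths
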