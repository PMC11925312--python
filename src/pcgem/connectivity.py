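"""Metabolite and gene connectivity of a metabolic network.

Connectivity of a metabolite is the number of reactions it participates
in; gene connectivity is the number of reactions whose gene-protein-
reaction (GPR) rule references the gene.  Because currency metabolites
(ATP, NAD(P)H, protons, small ions...) dominate the raw degree
distribution, the network can be pruned before counting: ubiquitous
species are deleted outright, substrate-product motifs (e.g. ATP ->
ADP hydrolysis coupling, NADPH/NADP redox pairs) are removed from any
reaction carrying the full pair on opposite sides, and transport
reactions can be dropped.  Rank-ordered degree distributions are
compared against the straight reference line joining the extremes in
(rank, log10 degree) space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import cobra
import numpy as np

from .gem_core import base_metabolite_id, is_pseudo_reaction

__all__ = [
    "ConnectivityRecord",
    "PruneSpec",
    "DEFAULT_PRUNE_SPEC",
    "metabolite_connectivity",
    "gene_connectivity",
    "prune_network",
    "reference_line_comparison",
]


@dataclass(frozen=True)
class ConnectivityRecord:
    """Degree of one metabolite or gene: the number of reactions it touches."""

    entity_id: str
    degree: int


@dataclass
class PruneSpec:
    """What to remove before a pruned connectivity calculation.

    ``remove_species`` and motif members are base metabolite ids
    (compartment tags stripped).  A motif pair is removed from a
    reaction only when both members appear on opposite sides of that
    reaction; partial matches leave the reaction untouched.
    """

    remove_species: list[str] = field(default_factory=list)
    remove_motifs: list[tuple[str, str]] = field(default_factory=list)
    remove_transport: bool = False


#: Currency species and coupling motifs removed by default: water,
#: protons, common inorganic ions and phosphate, plus ATP-hydrolysis
#: and redox substrate-product pairs.
DEFAULT_PRUNE_SPEC = PruneSpec(
    remove_species=["h2o", "h", "na1", "na", "k", "cl", "ca2", "mg2", "fe2", "fe3", "pi"],
    remove_motifs=[
        ("atp", "adp"),
        ("atp", "amp"),
        ("nad", "nadh"),
        ("nadp", "nadph"),
        ("gsh", "gssg"),
    ],
)


def metabolite_connectivity(
    model: cobra.Model, merge_compartments: bool = False
) -> list[ConnectivityRecord]:
    """Ranked metabolite degrees, pseudo-reactions excluded.

    The degree counts distinct reactions containing the metabolite with
    a nonzero coefficient.  With ``merge_compartments`` species sharing
    a base id are treated as one entity.  Records are sorted by
    decreasing degree, ties broken lexicographically by id.
    """
    counts: dict[str, set[str]] = {}
    for met in model.metabolites:
        key = base_metabolite_id(met) if merge_compartments else met.id
        counts.setdefault(key, set())
    for rxn in model.reactions:
        if is_pseudo_reaction(rxn):
            continue
        for met, coeff in rxn.metabolites.items():
            if coeff == 0:
                continue
            key = base_metabolite_id(met) if merge_compartments else met.id
            counts[key].add(rxn.id)
    records = [ConnectivityRecord(k, len(v)) for k, v in counts.items()]
    records.sort(key=lambda r: (-r.degree, r.entity_id))
    return records


def gene_connectivity(model: cobra.Model) -> list[ConnectivityRecord]:
    """Ranked gene degrees: reactions whose GPR references each gene."""
    counts = {gene.id: 0 for gene in model.genes}
    for rxn in model.reactions:
        for gene in rxn.genes:
            counts[gene.id] += 1
    records = [ConnectivityRecord(k, v) for k, v in counts.items()]
    records.sort(key=lambda r: (-r.degree, r.entity_id))
    return records


def prune_network(model: cobra.Model, spec: PruneSpec | None = None) -> cobra.Model:
    """Return a pruned copy of the model (the input is untouched).

    Listed species are deleted from every reaction; for each motif
    both members are stripped from any reaction containing the pair on
    opposite sides; with ``remove_transport`` reactions whose merged-
    compartment stoichiometry is all zeros are dropped.  Pruning is
    idempotent.
    """
    spec = spec if spec is not None else DEFAULT_PRUNE_SPEC
    model = model.copy()
    species = set(spec.remove_species)

    # motif removal first so species removal cannot break pair detection
    for rxn in model.reactions:
        for a, b in spec.remove_motifs:
            by_base: dict[str, float] = {}
            for met, coeff in rxn.metabolites.items():
                by_base.setdefault(base_metabolite_id(met), 0.0)
                by_base[base_metabolite_id(met)] += coeff
            if a in by_base and b in by_base and by_base[a] * by_base[b] < 0:
                drop = {
                    met: -coeff
                    for met, coeff in rxn.metabolites.items()
                    if base_metabolite_id(met) in (a, b)
                }
                rxn.add_metabolites(drop)

    to_strip = [m for m in model.metabolites if base_metabolite_id(m) in species]
    for met in to_strip:
        for rxn in list(met.reactions):
            rxn.add_metabolites({met: -rxn.metabolites[met]})
    model.remove_metabolites([m for m in to_strip if not m.reactions])

    if spec.remove_transport:
        drop_rxns = []
        for rxn in model.reactions:
            if is_pseudo_reaction(rxn) or not rxn.metabolites:
                continue
            merged: dict[str, float] = {}
            for met, coeff in rxn.metabolites.items():
                merged.setdefault(base_metabolite_id(met), 0.0)
                merged[base_metabolite_id(met)] += coeff
            if all(abs(v) < 1e-9 for v in merged.values()):
                drop_rxns.append(rxn)
        model.remove_reactions(drop_rxns)
    return model


def reference_line_comparison(
    dist_a: Sequence[int], dist_b: Sequence[int], tol: float = 1e-12
) -> dict[str, dict[str, int]]:
    """Count points strictly above/below the min-max reference line.

    Each distribution is rank-ordered (descending) and placed in
    (rank, log10 degree) space; the reference line joins (1, log10 max)
    to (N, log10 min).  Degenerate distributions (single point or all
    degrees equal) have zero points off the line.
    """
    out = {}
    for name, dist in (("a", dist_a), ("b", dist_b)):
        degrees = sorted((d for d in dist if d > 0), reverse=True)
        if not degrees:
            raise ValueError("distribution is empty")
        y = np.log10(np.asarray(degrees, dtype=float))
        n = len(y)
        if n == 1 or y[0] == y[-1]:
            out[name] = {"above": 0, "below": 0, "n": n}
            continue
        ranks = np.arange(1, n + 1)
        line = y[0] + (y[-1] - y[0]) * (ranks - 1) / (n - 1)
        out[name] = {
            "above": int(np.sum(y > line + tol)),
            "below": int(np.sum(y < line - tol)),
            "n": n,
        }
    return out
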