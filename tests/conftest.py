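import cobra
import pytest
from hypothesis import HealthCheck, settings

from pcgem.pc_build import build_pc_model
from pcgem.proteome_fit import normalize_to_budget, prepare_samples
from pcgem.synthetic_data import (
    SyntheticSpec,
    make_protein_tables,
    make_toy_gem,
    sample_donor_proteomes,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_model() -> cobra.Model:
    return make_toy_gem(seed=1)


@pytest.fixture(scope="session")
def protein_tables(toy_model):
    return make_protein_tables(toy_model, seed=1)


@pytest.fixture(scope="session")
def pc_model(toy_model, protein_tables):
    proteins, complexes = protein_tables
    return build_pc_model(toy_model, proteins, complexes)


@pytest.fixture(scope="session")
def small_panel(protein_tables):
    """A 6-donor synthetic panel with its planted truth."""
    proteins, _ = protein_tables
    spec = SyntheticSpec(n_donors=6, seed=11)
    raw, hb, metadata, truth = sample_donor_proteomes(proteins, spec)
    samples = prepare_samples(raw, hb)
    return {"spec": spec, "raw": raw, "hb": hb, "metadata": metadata,
            "truth": truth, "samples": samples}


@pytest.fixture(scope="session")
def fitted_sample(pc_model, small_panel):
    """One budget-normalized sample and its QP fit."""
    sample = small_panel["samples"][0]
    p_data = normalize_to_budget(sample, pc_model)
    fit = pc_model.fit(p_data)
    return sample, p_data, fit


def chain_model() -> cobra.Model:
    """Tiny linear chain: EX_A (uptake <= 10) -> A -> B -> export."""
    model = cobra.Model("chain")
    a = cobra.Metabolite("a_c", formula="C1", charge=0, compartment="c")
    b = cobra.Metabolite("b_c", formula="C1", charge=0, compartment="c")
    model.add_metabolites([a, b])
    for rid, stoich, bounds, gpr in [
        ("EX_a", {a: -1.0}, (-10.0, 1000.0), ""),
        ("AB", {a: -1.0, b: 1.0}, (0.0, 1000.0), "g1"),
        ("EX_b", {b: -1.0}, (0.0, 1000.0), ""),
    ]:
        rxn = cobra.Reaction(rid)
        model.add_reactions([rxn])
        rxn.add_metabolites(stoich)
        rxn.bounds = bounds
        if gpr:
            rxn.gene_reaction_rule = gpr
    model.objective = "EX_b"
    return model


@pytest.fixture()
def chain():
    return chain_model()
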