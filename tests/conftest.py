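import pytest

import copiascan as cs


@pytest.fixture(scope="session")
def panel():
    return cs.default_panel()


@pytest.fixture(scope="session")
def galea_element():
    """One canonical intact fungal GalEa element (CHS, 250 bp LTRs)."""
    return cs.make_element(cs.galea_spec(), seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    """120 kb genome with 4 GalEa (3 intact + 1 mutated) and 2 FunCo1
    implants, plus its truth table."""
    cfg = cs.SimConfig(
        seed=21, n_contigs=1, contig_len=120_000,
        plans=[
            cs.CopyPlan(cs.galea_spec("GalA"), {"intact": 3, "mutated": 1}),
            cs.CopyPlan(cs.funco1_spec("FunA", ltr_len=200, internal_len=5000),
                        {"intact": 2}),
        ])
    genome, truth = cs.simulate_dataset(cfg)
    return cfg, genome, truth
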