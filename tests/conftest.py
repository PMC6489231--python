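import numpy as np
import pytest

from metdep.synthetic import SyntheticConfig, generate

from helpers import make_model


@pytest.fixture
def chain_model():
    """R1: A->B (g1), R2: B->C (g2), R3: C->D (g3)."""
    return make_model([
        ("R1", ["A_c"], ["B_c"], "g1"),
        ("R2", ["B_c"], ["C_c"], "g2"),
        ("R3", ["C_c"], ["D_c"], "g3"),
    ])


@pytest.fixture
def mixed_rule_model():
    """10 reactions with mixed AND/OR rules, used for hand-enumerated checks."""
    return make_model([
        ("R01", ["A_c"], ["B_c"], "g1"),
        ("R02", ["B_c"], ["C_c"], "g1 or g2"),
        ("R03", ["C_c"], ["D_c"], "g3 and g4"),
        ("R04", ["D_c"], ["E_c"], "(g1 and g2) or g5"),
        ("R05", ["E_c"], ["F_c"], "g6 or (g7 and g8)"),
        ("R06", ["F_c"], ["G_c"], ""),
        ("R07", ["G_c"], ["H_c"], "g1 and (g2 or g3)"),
        ("R08", ["H_c"], ["A_c"], "g9"),
        ("R09", ["A_c", "C_c"], ["E_c"], "g10 or g11 or g12"),
        ("R10", ["B_c"], ["H_c"], "g2"),
    ])


@pytest.fixture(scope="session")
def synthetic_bundle():
    """One shared synthetic model + dataset with planted effects."""
    cfg = SyntheticConfig(seed=11, n_cell_lines=150, n_oncogenes=20)
    model, truth, _, _ = generate(cfg)
    genes = sorted(model.genes)
    target = max(truth.neighbors, key=lambda g: len(truth.neighbors[g]))
    partner = truth.neighbors[target][0]
    from metdep.synthetic import PlantedEffect

    cfg.planted_effects = [
        PlantedEffect("media_shift", genes[0], 2.0, condition="DMEM"),
        PlantedEffect("neighbor_expression", target, 2.0, partner=partner),
    ]
    model, truth, dataset, registry = generate(cfg)
    return {
        "config": cfg, "model": model, "truth": truth,
        "dataset": dataset, "registry": registry,
        "media_gene": genes[0], "neighbor_gene": target, "neighbor_partner": partner,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
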