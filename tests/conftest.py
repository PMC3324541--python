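import pytest

from ionrules import GenePanel, NeuronRecord
from ionrules.synth import PlantedRule, SynthConfig, generate


def make_record(i, layer="L2/3", morph="LBC", etype="cAD", bits=(0, 0, 0, 0)):
    return NeuronRecord(
        neuron_id=f"n{i}", layer=layer, morphology=morph, etype=etype,
        expression=tuple(bits))


@pytest.fixture
def panel4():
    return GenePanel(("Kv1.1", "Kv1.2", "HCN1", "HCN3"))


@pytest.fixture
def panel5():
    return GenePanel(("Kv1.4", "HCN3", "Kv3.1", "Kv3.2", "HCN1"))


@pytest.fixture
def planted_identity_records(panel5):
    """100 neurons, 2 LME types, Kv1.4 = HCN3 planted with 10% dropout."""
    cfg = SynthConfig(
        panel=panel5,
        group_counts={("L5", "MC", "cAD"): 50, ("L2/3", "LBC", "dFS"): 50},
        frequencies={"Kv1.4": 0.5, "HCN3": 0.5, "Kv3.1": 0.3,
                     "Kv3.2": 0.3, "HCN1": 0.3},
        planted_rules=(PlantedRule("Kv1.4", "HCN3"),),
        fn_rate=0.1, mode="planted", seed=7)
    return generate(cfg)
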