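import pytest

from myoflux.core import LARGE_BOUND, MetabolicNetwork, Metabolite, Reaction
from myoflux.disease import RegulationRecord
from myoflux.model import MuscleEnergyModel
from myoflux.synth import MiniMuscleConfig, build_mini_muscle, default_scenarios


@pytest.fixture(scope="session")
def mini_cfg():
    return MiniMuscleConfig()


@pytest.fixture(scope="session")
def mini_net(mini_cfg):
    return build_mini_muscle(mini_cfg)


@pytest.fixture(scope="session")
def graded_scenarios(mini_cfg):
    """Four graded-exercise scenarios with their ground truths."""
    return default_scenarios(mini_cfg)


@pytest.fixture(scope="session")
def fitted_control(mini_net, graded_scenarios):
    """Control model fitted once for the whole session (pure function of inputs)."""
    model = MuscleEnergyModel(
        mini_net, [s for s, _ in graded_scenarios], "EX_glc", "EX_fa", "EX_o2"
    )
    results = model.fit()
    assert not results.failures
    return results


@pytest.fixture(scope="session")
def demo_disease_records():
    """Mitochondrial-dysfunction-style regulation set used in worked examples:
    β-oxidation and respiratory NADH oxidation down-regulated, TCA flagged,
    the glycolytic lump's activity raised."""
    return [
        RegulationRecord("BETA_OX", "rnaseq", 0.5, "demo"),
        RegulationRecord("ETC_NADH", "rnaseq", 0.6, "demo"),
        RegulationRecord("TCA", "qualitative_warning", float("nan"), "demo"),
        RegulationRecord("GLYCOLYSIS", "activity", 133.0, "demo"),
    ]


@pytest.fixture(scope="session")
def disease_net(fitted_control, demo_disease_records):
    net, bounds, unmatched = fitted_control.build_disease_model(demo_disease_records)
    assert not unmatched
    return net


def single_fuel_network(net, fuel_exchange, cap, o2_cap=LARGE_BOUND):
    """Close every fuel uptake except one; O2 uptake capped at o2_cap."""
    out = net
    for ex in ("EX_glc", "EX_fa", "EX_kb", "EX_aa", "EX_glyc"):
        if not out.has_reaction(ex):
            continue
        out = out.set_bounds(ex, -cap if ex == fuel_exchange else 0.0, 0.0)
    return out.set_bounds("EX_o2", -o2_cap, 0.0)


@pytest.fixture(scope="session")
def chain_net():
    """uptake -> A -> demand, single bottleneck at the uptake."""
    mets = [Metabolite("A"), Metabolite("B")]
    rxns = [
        Reaction("in", {"A": -1}, -5.0, 0.0, is_exchange=True),
        Reaction("conv", {"A": -1, "B": 1}, 0.0, 100.0),
        Reaction("out", {"B": -1}, 0.0, 100.0),
    ]
    return MetabolicNetwork(mets, rxns, "out", name="chain")


@pytest.fixture(scope="session")
def diamond_net():
    """Two equal parallel branches carrying a total flux capped at 10."""
    mets = [Metabolite("A"), Metabolite("B")]
    rxns = [
        Reaction("src", {"A": -1}, -10.0, 0.0, is_exchange=True),
        Reaction("branch1", {"A": -1, "B": 1}, 0.0, 100.0),
        Reaction("branch2", {"A": -1, "B": 1}, 0.0, 100.0),
        Reaction("sink", {"B": -1}, 0.0, 100.0),
    ]
    return MetabolicNetwork(mets, rxns, "sink", name="diamond")
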