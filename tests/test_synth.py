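"""Mini-muscle generator: analytic yields are exact LP oracles."""

import numpy as np
import pytest

from myoflux.core import build_stoichiometric_matrix, fba
from myoflux.synth import (
    MiniMuscleConfig,
    analytic_yields,
    build_mini_muscle,
    default_scenarios,
    make_scenarios,
    sample_regulation_records,
)

from conftest import single_fuel_network


@pytest.mark.parametrize(
    "fuel,exchange",
    [
        ("glucose", "EX_glc"),
        ("fatty_acid", "EX_fa"),
        ("ketone_body", "EX_kb"),
        ("amino_acids", "EX_aa"),
        ("glycerol", "EX_glyc"),
    ],
)
def test_single_fuel_fba_matches_analytic_yields(mini_cfg, mini_net, fuel, exchange):
    atp, o2 = analytic_yields(mini_cfg, fuel)
    net = single_fuel_network(mini_net, exchange, 1.0)
    sol = fba(net)
    assert sol.objective_value == pytest.approx(atp, abs=1e-6)
    assert -sol.fluxes["EX_o2"] == pytest.approx(o2, abs=1e-6)


def test_default_yields_are_textbook(mini_cfg):
    assert analytic_yields(mini_cfg, "glucose") == (32.0, 6.0)
    assert analytic_yields(mini_cfg, "fatty_acid") == (106.0, 23.0)


def test_anaerobic_glucose(mini_net):
    net = single_fuel_network(mini_net, "EX_glc", 1.0, o2_cap=0.0)
    sol = fba(net)
    assert sol.objective_value == pytest.approx(2.0, abs=1e-8)
    assert sol.fluxes["EX_lac"] == pytest.approx(2.0, abs=1e-6)


def test_zero_uptake_caps_zero_atp(mini_net):
    net = mini_net
    for ex in ("EX_glc", "EX_fa", "EX_kb", "EX_aa", "EX_glyc"):
        net = net.set_bounds(ex, 0.0, 0.0)
    assert fba(net).objective_value == pytest.approx(0.0, abs=1e-9)


def test_internal_metabolites_balanced_by_construction(mini_net):
    sol = fba(mini_net)
    S = build_stoichiometric_matrix(mini_net)
    v = np.array([sol.fluxes[r.id] for r in mini_net.reactions])
    assert np.max(np.abs(S @ v)) <= 1e-8


def test_yields_scale_with_po_ratio():
    base = MiniMuscleConfig()
    doubled = MiniMuscleConfig(po_nadh=5.0)
    atp0, _ = analytic_yields(base, "glucose")
    atp1, _ = analytic_yields(doubled, "glucose")
    # glucose oxidation moves 8 NADH through the mitochondrial chain
    assert atp1 - atp0 == pytest.approx(8 * 2.5)
    net = build_mini_muscle(doubled)
    sol = fba(single_fuel_network(net, "EX_glc", 1.0))
    assert sol.objective_value == pytest.approx(atp1, abs=1e-6)


def test_config_validation():
    with pytest.raises(ValueError):
        MiniMuscleConfig(po_nadh=0.0)
    with pytest.raises(ValueError):
        MiniMuscleConfig(substrates=("glucose", "starlight"))
    with pytest.raises(ValueError):
        MiniMuscleConfig(default_uptake_caps={"glucose": -1})
    with pytest.raises(KeyError):
        analytic_yields(MiniMuscleConfig(substrates=("glucose",)), "fatty_acid")


def test_substrate_menu_is_configurable():
    cfg = MiniMuscleConfig(substrates=("glucose", "fatty_acid"))
    net = build_mini_muscle(cfg)
    assert not net.has_reaction("EX_kb")
    assert not net.has_reaction("KETOLYSIS")
    assert fba(net).optimal


# -- scenario generation --------------------------------------------------------

def test_scenarios_implied_quantities(mini_cfg):
    [(scen, truth)] = make_scenarios(mini_cfg, [(1.0, 0.0)])
    assert scen.target_cho_share == pytest.approx(1.0)
    assert scen.atp_flux == pytest.approx(32.0)
    assert scen.o2_flux == pytest.approx(-6.0)
    # equal ATP contributions -> half/half share
    [(scen2, _)] = make_scenarios(mini_cfg, [(1.0, 32.0 / 106.0)])
    assert scen2.target_cho_share == pytest.approx(0.5)


def test_scenarios_monotone_with_demand(mini_cfg):
    pairs = [(0.2, 0.05), (0.5, 0.1), (1.0, 0.12), (2.0, 0.15)]
    out = make_scenarios(mini_cfg, pairs)
    atps = [s.atp_flux for s, _ in out]
    o2s = [-s.o2_flux for s, _ in out]
    assert atps == sorted(atps)
    assert o2s == sorted(o2s)


def test_degenerate_scenario_rejected(mini_cfg):
    with pytest.raises(ValueError, match="degenerate"):
        make_scenarios(mini_cfg, [(0.0, 0.0)])


def test_default_scenarios_use_graded_demands(mini_cfg):
    out = default_scenarios(mini_cfg)
    assert [s.percent_vo2max for s, _ in out] == [25.0, 65.0, 85.0, 100.0]
    assert [s.atp_flux for s, _ in out] == [14.6, 36.52, 54.8, 75.0]
    assert [round(s.target_cho_share, 2) for s, _ in out] == [0.4, 0.5, 0.8, 1.0]
    for s, t in out:
        assert t.implied_atp == pytest.approx(s.atp_flux)


# -- regulation sampling ----------------------------------------------------------

def test_regulation_sampling_reproducible():
    a = sample_regulation_records(seed=1, n=18)
    b = sample_regulation_records(seed=1, n=18)
    assert a == b
    assert len(a) == 18
    c = sample_regulation_records(seed=2, n=18)
    assert a != c


def test_regulation_sampling_respects_factor_range():
    from myoflux.disease import correction_factor

    records = sample_regulation_records(seed=3, n=40, factor_range=(0.5, 2.0))
    factors = [correction_factor(r) for r in records]
    assert all(0.5 <= f <= 2.0 for f in factors)
    assert any(f < 1 for f in factors) and any(f > 1 for f in factors)


def test_unit_factor_records_leave_model_unchanged(fitted_control, mini_net):
    from myoflux.disease import control_max_profile, apply_disease_constraints
    from myoflux.core import fba

    records = sample_regulation_records(seed=4, n=6, factor_range=(1.0, 1.0))
    profile = control_max_profile(fitted_control.control_solutions())
    disease, bounds, _ = apply_disease_constraints(mini_net, profile, records)
    assert all(b.correction_factor == 1.0 for b in bounds)
    # caps equal control maxima, so the unconstrained optimum cannot drop below
    # any flux the control solutions realised
    for b in bounds:
        assert b.disease_upper_bound == pytest.approx(b.control_max_flux)


def test_halved_beta_oxidation_halves_fat_only_atp(mini_net):
    from myoflux.disease import apply_disease_constraints, RegulationRecord

    fat_only = single_fuel_network(mini_net, "EX_fa", 1.0)
    control_atp = fba(fat_only).objective_value
    profile = {"BETA_OX": abs(fba(fat_only).fluxes["BETA_OX"])}
    disease, _, _ = apply_disease_constraints(
        fat_only, profile, [RegulationRecord("BETA_OX", "rnaseq", 0.5, "")]
    )
    # β-oxidation feeds everything downstream of the sole fuel, and the ATP
    # yield (activation cost included) is linear in the fuel burned: halving
    # the β-ox cap halves the achievable ATP
    disease_atp = fba(disease).objective_value
    assert disease_atp == pytest.approx(0.5 * control_atp, abs=1e-6)


def test_regulation_sampling_errors():
    with pytest.raises(ValueError):
        sample_regulation_records(n=0)
    with pytest.raises(ValueError):
        sample_regulation_records(factor_range=(0.0, 1.0))
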