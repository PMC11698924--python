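"""LP core: stoichiometric matrix, FBA, FVA, bound handling."""

import numpy as np
import pytest

from myoflux.core import (
    MetabolicNetwork,
    Metabolite,
    Reaction,
    StructuralError,
    build_stoichiometric_matrix,
    fba,
    fva,
    set_reaction_bounds,
)

from lp_oracle import brute_force_fba, brute_force_fva


def _lp_arrays(net):
    S = build_stoichiometric_matrix(net)
    lb = np.array([r.lower_bound for r in net.reactions])
    ub = np.array([r.upper_bound for r in net.reactions])
    return S, lb, ub


# -- structure ---------------------------------------------------------------

def test_stoichiometric_matrix_chain():
    mets = [Metabolite("A"), Metabolite("B")]
    rxns = [
        Reaction("in", {"A": 1}, 0, 10),
        Reaction("convert", {"A": -1, "B": 1}, 0, 10),
        Reaction("out", {"B": -1}, 0, 10),
    ]
    net = MetabolicNetwork(mets, rxns, "out")
    S = build_stoichiometric_matrix(net)
    assert S.shape == (2, 3)
    np.testing.assert_array_equal(S, [[1, -1, 0], [0, 1, -1]])


def test_stoichiometric_matrix_excludes_boundary_rows():
    mets = [Metabolite("A"), Metabolite("A_ext", is_boundary=True)]
    rxns = [Reaction("t", {"A_ext": -1, "A": 1}, 0, 10), Reaction("sink", {"A": -1}, 0, 10)]
    net = MetabolicNetwork(mets, rxns, "sink")
    assert build_stoichiometric_matrix(net).shape == (1, 2)


def test_empty_network_matrix():
    mets = [Metabolite("A")]
    net = MetabolicNetwork(mets, [Reaction("r", {"A": 0.0}, 0, 1)], "r")
    sub = MetabolicNetwork([], [Reaction("r", {}, 0, 1)], "r")
    assert build_stoichiometric_matrix(sub).shape == (0, 1)
    assert build_stoichiometric_matrix(net).shape == (1, 1)


@pytest.mark.parametrize(
    "bad",
    [
        dict(mets=[Metabolite("A")], rxns=[Reaction("r", {"ghost": 1}, 0, 1)], obj="r"),
        dict(mets=[Metabolite("A")], rxns=[Reaction("r", {"A": 1}, 0, 1)], obj="missing"),
        dict(
            mets=[Metabolite("A"), Metabolite("A")],
            rxns=[Reaction("r", {"A": 1}, 0, 1)],
            obj="r",
        ),
    ],
)
def test_structural_errors(bad):
    with pytest.raises(StructuralError):
        MetabolicNetwork(bad["mets"], bad["rxns"], bad["obj"])


def test_inverted_bounds_rejected():
    with pytest.raises(StructuralError):
        Reaction("r", {"A": 1}, 1.0, 0.0)


# -- FBA ----------------------------------------------------------------------

def test_fba_chain_bottleneck(chain_net):
    sol = fba(chain_net)
    assert sol.optimal
    assert sol.objective_value == pytest.approx(5.0)
    assert sol.fluxes["in"] == pytest.approx(-5.0)


def test_fba_mini_muscle_glucose_yield(mini_net):
    from conftest import single_fuel_network

    net = single_fuel_network(mini_net, "EX_glc", 1.0)
    sol = fba(net)
    assert sol.objective_value == pytest.approx(32.0, abs=1e-6)


def test_fba_status_infeasible():
    mets = [Metabolite("A")]
    # forced production with no consumer
    rxns = [Reaction("make", {"A": 1}, 1.0, 2.0), Reaction("obj", {"A": -1}, 0.0, 0.0)]
    net = MetabolicNetwork(mets, rxns, "obj")
    assert fba(net).status == "infeasible"


def test_fba_mass_balance_and_bounds(mini_net):
    sol = fba(mini_net)
    S, lb, ub = _lp_arrays(mini_net)
    v = np.array([sol.fluxes[r.id] for r in mini_net.reactions])
    assert np.max(np.abs(S @ v)) <= 1e-8
    assert np.all(v >= lb - 1e-9) and np.all(v <= ub + 1e-9)


def test_parsimonious_solution_is_deterministic(diamond_net):
    a = fba(diamond_net)
    b = fba(diamond_net)
    assert a.fluxes == b.fluxes
    # parsimony splits nothing extra: total flux is minimal, so no futile cycle
    assert a.objective_value == pytest.approx(10.0)


def test_blocked_reaction_carries_zero_flux(mini_net):
    net = set_reaction_bounds(mini_net, "BETA_OX", 0.0, 0.0)
    sol = fba(net)
    assert sol.fluxes["BETA_OX"] == pytest.approx(0.0, abs=1e-12)


def test_set_bounds_value_semantics(mini_net):
    before = mini_net.reaction("EX_glc").lower_bound
    new = set_reaction_bounds(mini_net, "EX_glc", -0.03, 0.0)
    assert mini_net.reaction("EX_glc").lower_bound == before
    assert new.reaction("EX_glc").lower_bound == -0.03
    sol = fba(new)
    assert sol.fluxes["EX_glc"] >= -0.03 - 1e-9


def test_set_bounds_errors(mini_net):
    with pytest.raises(KeyError):
        set_reaction_bounds(mini_net, "nope", 0, 1)
    with pytest.raises(StructuralError):
        set_reaction_bounds(mini_net, "EX_glc", 1.0, -1.0)


def test_relaxation_monotonicity(mini_net):
    """Widening any bound never decreases the FBA optimum."""
    rng = np.random.default_rng(42)
    base = fba(mini_net).objective_value
    rids = mini_net.reaction_ids
    for _ in range(100):
        rid = rids[int(rng.integers(len(rids)))]
        rxn = mini_net.reaction(rid)
        widen_lo = rxn.lower_bound - float(rng.uniform(0, 5))
        widen_hi = rxn.upper_bound + float(rng.uniform(0, 5))
        relaxed = mini_net.set_bounds(rid, widen_lo, widen_hi)
        assert fba(relaxed).objective_value >= base - 1e-6


# -- FVA ----------------------------------------------------------------------

def test_fva_chain_fully_determined(chain_net):
    fr = fva(chain_net)
    for rid in chain_net.reaction_ids:
        assert fr.width(rid) == pytest.approx(0.0, abs=1e-7)


def test_fva_diamond_branch_ranges(diamond_net):
    fr = fva(diamond_net, reactions=["branch1", "branch2"])
    for rid in ("branch1", "branch2"):
        lo, hi = fr[rid]
        assert lo == pytest.approx(0.0, abs=1e-7)
        assert hi == pytest.approx(10.0, abs=1e-7)


def test_fva_contains_fba_flux(mini_net):
    sol = fba(mini_net)
    fr = fva(mini_net)
    for rid, (lo, hi) in fr.ranges.items():
        assert lo - 1e-6 <= sol.fluxes[rid] <= hi + 1e-6


def test_fva_extreme_fixing_preserves_optimum(diamond_net):
    z = fba(diamond_net).objective_value
    fr = fva(diamond_net, reactions=["branch1"])
    for extreme in fr["branch1"]:
        pinned = diamond_net.set_bounds("branch1", extreme, extreme)
        z2 = fba(pinned).objective_value
        assert z2 == pytest.approx(z, rel=1e-6)


def test_fva_rejects_bad_fraction(mini_net):
    with pytest.raises(ValueError):
        fva(mini_net, fraction_of_optimum=0.0)


# -- oracle equivalence --------------------------------------------------------

def _random_small_network(rng):
    n_mets = int(rng.integers(1, 4))
    n_rxns = int(rng.integers(2, 7))
    mets = [Metabolite(f"m{i}") for i in range(n_mets)]
    rxns = []
    for j in range(n_rxns):
        stoich = {
            f"m{i}": int(c)
            for i, c in enumerate(rng.integers(-2, 3, size=n_mets))
            if c != 0
        }
        lo = float(rng.choice([-5.0, -2.0, 0.0]))
        hi = float(rng.choice([0.0, 2.0, 5.0]))
        rxns.append(Reaction(f"r{j}", stoich, min(lo, hi), max(lo, hi)))
    return MetabolicNetwork(mets, rxns, "r0")


def test_fba_fva_match_vertex_enumeration():
    """On ≤6-reaction random networks, LP answers equal brute-force
    enumeration of the flux-polytope vertices."""
    rng = np.random.default_rng(2024)
    checked = 0
    for _ in range(40):
        net = _random_small_network(rng)
        S, lb, ub = _lp_arrays(net)
        sol = fba(net, parsimonious=False)
        assert sol.optimal  # v = 0 is always feasible here
        z_oracle = brute_force_fba(S, lb, ub, 0)
        assert sol.objective_value == pytest.approx(z_oracle, abs=1e-6)
        if abs(z_oracle) > 1e-9:
            fr = fva(net)
            oracle_ranges = brute_force_fva(S, lb, ub, 0)
            for j, rxn in enumerate(net.reactions):
                lo, hi = fr[rxn.id]
                assert lo == pytest.approx(oracle_ranges[j][0], abs=1e-6)
                assert hi == pytest.approx(oracle_ranges[j][1], abs=1e-6)
            checked += 1
    assert checked >= 10  # enough nondegenerate cases exercised
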