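"""Stoichiometric network representation and the linear-programming core.

A :class:`MetabolicNetwork` is a plain stoichiometric model: metabolites
(with compartments), reactions (with flux bounds in μmol·gDW⁻¹·min⁻¹) and a
designated objective reaction (typically the ATP demand).  Flux balance
analysis (FBA) maximises or minimises the objective flux subject to
steady-state mass balance ``S·v = 0`` and the per-reaction bounds; flux
variability analysis (FVA) reports, per reaction, the min and max flux
compatible with near-optimal objective values.

Sign convention: uptake through an exchange reaction is a *negative* flux;
"uptake magnitude" always means ``abs(flux)``.

Degenerate optima are resolved parsimoniously: after optimising the
objective, the total absolute flux ``Σ|v|`` is secondarily minimised so a
reported distribution is reproducible across solvers.  FVA remains the
authoritative statement of variability.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "LARGE_BOUND",
    "COMPARTMENTS",
    "PATHWAY_TAGS",
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "FluxDistribution",
    "FluxRange",
    "StructuralError",
    "InfeasibleProblemError",
    "UnboundedProblemError",
    "build_stoichiometric_matrix",
    "fba",
    "fva",
    "set_reaction_bounds",
]

#: Finite sentinel standing in for an unbounded flux cap (keeps every LP bounded).
LARGE_BOUND = 1000.0

COMPARTMENTS = ("cytosol", "mitochondrion", "extracellular")
PATHWAY_TAGS = (
    "glycolysis",
    "beta_oxidation",
    "tca",
    "oxphos",
    "ketone",
    "amino_acid",
    "transport",
    "exchange",
    "other",
)

#: LP feasibility/optimality tolerance handed to HiGHS.
LP_TOLERANCE = 1e-9
#: Tolerance on the steady-state residual ``‖S·v‖∞`` of an optimal solution.
MASS_BALANCE_TOLERANCE = 1e-8


class StructuralError(ValueError):
    """The network violates a structural invariant (dangling reference, bad bounds...)."""


class InfeasibleProblemError(RuntimeError):
    """The LP constraint set admits no solution; carries scenario context when known."""

    def __init__(self, message: str, context: object = None):
        super().__init__(message)
        self.context = context


class UnboundedProblemError(RuntimeError):
    """The objective is unbounded (a bound sentinel is missing somewhere)."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "cytosol"
    is_boundary: bool = False

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise StructuralError(
                f"metabolite {self.id!r}: compartment {self.compartment!r} "
                f"not in {COMPARTMENTS}"
            )


@dataclass(frozen=True)
class Reaction:
    """One reaction: signed stoichiometry plus flux bounds.

    ``stoichiometry`` maps metabolite id → coefficient (negative = consumed).
    Exchange reactions touch exactly one non-boundary metabolite; a negative
    exchange flux imports that metabolite.
    """

    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = 0.0
    upper_bound: float = LARGE_BOUND
    name: str = ""
    ec_number: str | None = None
    pathway_tag: str | None = None
    is_exchange: bool = False

    def __post_init__(self):
        if self.lower_bound > self.upper_bound:
            raise StructuralError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if self.pathway_tag is not None and self.pathway_tag not in PATHWAY_TAGS:
            raise StructuralError(
                f"reaction {self.id!r}: unknown pathway tag {self.pathway_tag!r}"
            )
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))

    def with_bounds(self, lower: float, upper: float) -> "Reaction":
        if lower > upper:
            raise StructuralError(
                f"reaction {self.id!r}: inverted bounds ({lower}, {upper})"
            )
        return replace(self, lower_bound=float(lower), upper_bound=float(upper))


class MetabolicNetwork:
    """A stoichiometric model with bounds and an objective (ATP demand) reaction.

    Value semantics: mutating operations (:meth:`set_bounds`,
    :func:`set_reaction_bounds`) return a modified copy and never touch the
    original.
    """

    def __init__(
        self,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        objective_reaction_id: str,
        name: str = "",
    ):
        self.metabolites: list[Metabolite] = list(metabolites)
        self.reactions: list[Reaction] = list(reactions)
        self.objective_reaction_id = objective_reaction_id
        self.name = name
        self._validate()

    # -- structure ---------------------------------------------------------
    def _validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise StructuralError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise StructuralError(f"duplicate reaction ids: {dup}")
        met_set = set(met_ids)
        boundary = {m.id for m in self.metabolites if m.is_boundary}
        for rxn in self.reactions:
            for met in rxn.stoichiometry:
                if met not in met_set:
                    raise StructuralError(
                        f"reaction {rxn.id!r} references unknown metabolite {met!r}"
                    )
            if rxn.is_exchange:
                internal = [m for m in rxn.stoichiometry if m not in boundary]
                if len(internal) != 1:
                    raise StructuralError(
                        f"exchange reaction {rxn.id!r} must touch exactly one "
                        f"non-boundary metabolite, found {internal}"
                    )
        if self.objective_reaction_id not in set(rxn_ids):
            raise StructuralError(
                f"objective reaction {self.objective_reaction_id!r} not in network"
            )

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def internal_metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if not m.is_boundary]

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def has_reaction(self, rxn_id: str) -> bool:
        return any(r.id == rxn_id for r in self.reactions)

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            list(self.metabolites),
            [_copy.copy(r) for r in self.reactions],
            self.objective_reaction_id,
            name=self.name,
        )

    def set_bounds(self, rxn_id: str, lower: float, upper: float) -> "MetabolicNetwork":
        """Return a copy with one reaction's bounds replaced (original untouched)."""
        if not self.has_reaction(rxn_id):
            raise KeyError(f"unknown reaction id {rxn_id!r}")
        new_reactions = [
            r.with_bounds(lower, upper) if r.id == rxn_id else r for r in self.reactions
        ]
        return MetabolicNetwork(
            list(self.metabolites), new_reactions, self.objective_reaction_id, self.name
        )

    def remove_reactions(self, rxn_ids: Iterable[str]) -> "MetabolicNetwork":
        drop = set(rxn_ids)
        if self.objective_reaction_id in drop:
            raise StructuralError("cannot remove the objective reaction")
        return MetabolicNetwork(
            list(self.metabolites),
            [r for r in self.reactions if r.id not in drop],
            self.objective_reaction_id,
            self.name,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<MetabolicNetwork {self.name or 'unnamed'}: "
            f"{len(self.metabolites)} metabolites, {len(self.reactions)} reactions>"
        )


@dataclass
class FluxDistribution:
    """One FBA solution: reaction fluxes, objective value and solver status."""

    fluxes: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FluxRange:
    """FVA output: per-reaction (min, max) flux at a given fraction of the optimum."""

    ranges: dict[str, tuple[float, float]]
    fraction_of_optimum: float = 1.0

    def __getitem__(self, rxn_id: str) -> tuple[float, float]:
        return self.ranges[rxn_id]

    def width(self, rxn_id: str) -> float:
        lo, hi = self.ranges[rxn_id]
        return hi - lo


def build_stoichiometric_matrix(network: MetabolicNetwork) -> np.ndarray:
    """Dense stoichiometric matrix S; rows are internal (non-boundary) metabolites,
    columns follow ``network.reactions`` order."""
    rows = network.internal_metabolite_ids
    row_index = {m: i for i, m in enumerate(rows)}
    S = np.zeros((len(rows), len(network.reactions)))
    for j, rxn in enumerate(network.reactions):
        for met, coeff in rxn.stoichiometry.items():
            i = row_index.get(met)
            if i is not None:
                S[i, j] = coeff
    return S


_LINPROG_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _solve(c, S, bounds, extra_A_ub=None, extra_b_ub=None):
    A_ub = extra_A_ub
    b_ub = extra_b_ub
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
        options={
            "primal_feasibility_tolerance": LP_TOLERANCE,
            "dual_feasibility_tolerance": LP_TOLERANCE,
        },
    )
    return res


def fba(
    network: MetabolicNetwork,
    objective_reaction: str | None = None,
    sense: str = "maximize",
    parsimonious: bool = True,
) -> FluxDistribution:
    """Flux balance analysis: optimise one reaction's flux at steady state.

    Maximises (or minimises) the flux through ``objective_reaction`` subject
    to ``S·v = 0`` and the per-reaction bounds.  When ``parsimonious`` is
    set (the default), the total absolute flux ``Σ|v|`` is secondarily
    minimised at the optimal objective, making the returned distribution a
    deterministic representative of a possibly degenerate optimal face.

    Returns a :class:`FluxDistribution` whose ``status`` reflects the solver
    outcome (``optimal``, ``infeasible`` or ``unbounded``); non-optimal
    statuses carry empty fluxes rather than raising, so callers can attach
    scenario context before deciding to fail.
    """
    obj_id = objective_reaction or network.objective_reaction_id
    if not network.has_reaction(obj_id):
        raise KeyError(f"objective reaction {obj_id!r} not in network")
    if sense not in ("maximize", "minimize"):
        raise ValueError(f"sense must be 'maximize' or 'minimize', got {sense!r}")

    S = build_stoichiometric_matrix(network)
    n = len(network.reactions)
    idx = {r.id: j for j, r in enumerate(network.reactions)}
    bounds = [(r.lower_bound, r.upper_bound) for r in network.reactions]
    c = np.zeros(n)
    c[idx[obj_id]] = -1.0 if sense == "maximize" else 1.0

    res = _solve(c, S, bounds)
    status = _LINPROG_STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxDistribution({}, float("nan"), status)

    z = float(res.x[idx[obj_id]])
    v = res.x
    if parsimonious:
        v = _parsimonious_solution(S, bounds, idx[obj_id], z, sense)
        if v is None:  # numerically marginal; fall back to the primary solution
            v = res.x
    fluxes = {r.id: float(v[j]) for j, r in enumerate(network.reactions)}
    return FluxDistribution(fluxes, z, "optimal")


def _parsimonious_solution(S, bounds, obj_idx, z, sense):
    """Minimise Σ|v| with the objective pinned at its optimum z.

    Variables are (v, t) with t >= |v| elementwise; the objective pin is a
    one-sided inequality slackened by a small absolute/relative tolerance so
    the second LP cannot go infeasible through round-off.
    """
    n = S.shape[1]
    slack = 1e-9 * max(1.0, abs(z))
    S2 = np.hstack([S, np.zeros((S.shape[0], n))])
    # t >= v  and  t >= -v   <=>   v - t <= 0  and  -v - t <= 0
    I = np.eye(n)
    A_ub = np.vstack(
        [
            np.hstack([I, -I]),
            np.hstack([-I, -I]),
        ]
    )
    b_ub = np.zeros(2 * n)
    pin_row = np.zeros(2 * n)
    pin_row[obj_idx] = -1.0 if sense == "maximize" else 1.0
    rhs = -(z - slack) if sense == "maximize" else (z + slack)
    A_ub = np.vstack([A_ub, pin_row])
    b_ub = np.append(b_ub, rhs)

    big = max(max(abs(lo), abs(hi)) for lo, hi in bounds) if bounds else 1.0
    var_bounds = list(bounds) + [(0.0, big)] * n
    cost = np.concatenate([np.zeros(n), np.ones(n)])
    res = linprog(
        cost,
        A_eq=S2,
        b_eq=np.zeros(S.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=var_bounds,
        method="highs",
        options={
            "primal_feasibility_tolerance": LP_TOLERANCE,
            "dual_feasibility_tolerance": LP_TOLERANCE,
        },
    )
    if res.status != 0:
        return None
    return res.x[:n]


def fva(
    network: MetabolicNetwork,
    objective_reaction: str | None = None,
    fraction_of_optimum: float = 1.0,
    reactions: Sequence[str] | None = None,
) -> FluxRange:
    """Flux variability analysis at a fraction of the FBA optimum.

    For each requested reaction the min and max flux are computed subject to
    the FBA constraints plus ``objective >= fraction_of_optimum * optimum``
    (for a maximisation objective; the inequality is flipped when the
    optimum is negative so the constraint always retains near-optimality).

    Raises :class:`InfeasibleProblemError` / :class:`UnboundedProblemError`
    when the base FBA problem is not optimal.
    """
    if not 0 < fraction_of_optimum <= 1:
        raise ValueError("fraction_of_optimum must lie in (0, 1]")
    obj_id = objective_reaction or network.objective_reaction_id
    base = fba(network, obj_id, parsimonious=False)
    if base.status == "infeasible":
        raise InfeasibleProblemError(
            f"base FBA problem infeasible for objective {obj_id!r}", context=network.name
        )
    if base.status != "optimal":
        raise UnboundedProblemError(f"base FBA problem is {base.status}")

    z = base.objective_value
    # objective >= frac * z, written as -v_obj <= -threshold
    threshold = fraction_of_optimum * z if z >= 0 else z / fraction_of_optimum

    S = build_stoichiometric_matrix(network)
    n = len(network.reactions)
    idx = {r.id: j for j, r in enumerate(network.reactions)}
    bounds = [(r.lower_bound, r.upper_bound) for r in network.reactions]
    row = np.zeros((1, n))
    row[0, idx[obj_id]] = -1.0
    b = np.array([-threshold])

    wanted = list(reactions) if reactions is not None else network.reaction_ids
    ranges: dict[str, tuple[float, float]] = {}
    for rid in wanted:
        if rid not in idx:
            raise KeyError(f"unknown reaction id {rid!r}")
        c = np.zeros(n)
        c[idx[rid]] = 1.0
        lo = _solve(c, S, bounds, row, b)
        hi = _solve(-c, S, bounds, row, b)
        if lo.status != 0 or hi.status != 0:
            raise InfeasibleProblemError(
                f"FVA subproblem failed for reaction {rid!r}", context=obj_id
            )
        vmin, vmax = float(lo.x[idx[rid]]), float(hi.x[idx[rid]])
        if vmin > vmax:  # round-off on a fixed flux
            vmin = vmax = 0.5 * (vmin + vmax)
        ranges[rid] = (vmin, vmax)
    return FluxRange(ranges, fraction_of_optimum)


def set_reaction_bounds(
    network: MetabolicNetwork, rxn_id: str, lower: float, upper: float
) -> MetabolicNetwork:
    """Functional bound update: returns a new network, original left unmodified."""
    return network.set_bounds(rxn_id, lower, upper)
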