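"""Intensity sweeps, nutrient-bound lifting and ATP-recovery quantification.

The disease network, given the same nutrient uptake caps as the healthy
(control) model, under-produces ATP at higher exercise intensities.  This
module sweeps exercise intensities (O2 fixed per intensity, ATP demand
maximised under the caps), then lifts the uptake caps of chosen nutrient
sets to the large-bound sentinel and measures how closely the resulting ATP
curve approaches the control curve, summarised by the root-mean-square error
over intensities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .core import (
    LARGE_BOUND,
    FluxDistribution,
    FluxRange,
    MetabolicNetwork,
    fba,
    fva,
)
from .fitting import IntensityScenario

__all__ = [
    "SweepResult",
    "CompensationReport",
    "run_intensity_sweep",
    "lift_bounds_scan",
    "rmse",
    "variability_report",
]


@dataclass
class SweepResult:
    """Maximal ATP per intensity under a fixed set of nutrient uptake caps."""

    atp_by_intensity: dict[float, float]
    solutions: dict[float, FluxDistribution]
    lifted_nutrients: frozenset[str] = frozenset()
    infeasible_intensities: list[float] = field(default_factory=list)


@dataclass
class CompensationReport:
    """Baseline sweep plus bound-lifting scans with their RMSE to control."""

    baseline: SweepResult
    scans: list[SweepResult]
    rmse_by_scan: dict[frozenset[str], float]
    control_reference: dict[float, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sweep in [self.baseline, *self.scans]:
            key = frozenset(sweep.lifted_nutrients)
            label = "+".join(sorted(sweep.lifted_nutrients)) or "baseline"
            for pct, atp in sweep.atp_by_intensity.items():
                rows.append(
                    {
                        "lifted_set": label,
                        "percent_vo2max": pct,
                        "atp_flux": atp,
                        "control_atp_flux": self.control_reference.get(pct),
                        "rmse": self.rmse_by_scan[key],
                    }
                )
        return pd.DataFrame(rows)


def _caps_for(
    uptake_caps: Mapping, label: float
) -> Mapping[str, float]:
    """Accept either one flat {exchange: cap} mapping or one keyed by intensity."""
    if not uptake_caps:
        return {}
    sample = next(iter(uptake_caps.values()))
    if isinstance(sample, Mapping):
        if label not in uptake_caps:
            raise KeyError(f"no uptake caps for intensity {label}")
        return uptake_caps[label]
    return uptake_caps


def run_intensity_sweep(
    network: MetabolicNetwork,
    scenarios: Sequence[IntensityScenario],
    uptake_caps: Mapping,
    o2_exchange: str,
    lifted_nutrients: frozenset[str] = frozenset(),
    large_bound: float = LARGE_BOUND,
) -> SweepResult:
    """Maximise ATP at each intensity under nutrient uptake caps.

    Per scenario the O2 uptake is capped at the scenario magnitude (a bound,
    not an equality: a constrained network may consume less), each capped
    fuel exchange gets bounds ``[-cap, 0]`` (members of ``lifted_nutrients``
    get ``[-large_bound, 0]`` instead), and the ATP demand — deliberately
    *not* fixed — is maximised up to the scenario's demanded flux (a cell
    meets its demand, it does not overproduce; a healthy network under its
    own fitted caps therefore reproduces the scenario ATP targets exactly,
    and a constrained one falls short).  Infeasible intensities are flagged
    and the sweep continues.
    """
    atp: dict[float, float] = {}
    sols: dict[float, FluxDistribution] = {}
    infeasible: list[float] = []
    for scen in scenarios:
        caps = _caps_for(uptake_caps, scen.percent_vo2max)
        net = network.set_bounds(o2_exchange, scen.o2_flux, 0.0)
        net = net.set_bounds(network.objective_reaction_id, 0.0, scen.atp_flux)
        for ex, cap in caps.items():
            if not network.has_reaction(ex):
                continue
            magnitude = large_bound if ex in lifted_nutrients else abs(cap)
            net = net.set_bounds(ex, -magnitude, 0.0)
        for ex in lifted_nutrients:
            if network.has_reaction(ex) and ex not in caps:
                net = net.set_bounds(ex, -large_bound, 0.0)
        sol = fba(net)
        sols[scen.percent_vo2max] = sol
        if sol.optimal:
            atp[scen.percent_vo2max] = sol.objective_value
        else:
            atp[scen.percent_vo2max] = float("nan")
            infeasible.append(scen.percent_vo2max)
    return SweepResult(atp, sols, frozenset(lifted_nutrients), infeasible)


def rmse(curve_a: Mapping[float, float], curve_b: Mapping[float, float]) -> float:
    """Root-mean-square difference between two equal-keyed intensity curves."""
    if set(curve_a) != set(curve_b):
        raise KeyError(
            f"mismatched intensity keys: {sorted(curve_a)} vs {sorted(curve_b)}"
        )
    if not curve_a:
        raise ValueError("empty curves")
    sq = [(curve_a[k] - curve_b[k]) ** 2 for k in curve_a]
    return math.sqrt(sum(sq) / len(sq))


def lift_bounds_scan(
    network: MetabolicNetwork,
    scenarios: Sequence[IntensityScenario],
    uptake_caps: Mapping,
    o2_exchange: str,
    nutrient_sets: Sequence[frozenset[str] | set[str]],
    control_reference: Mapping[float, float],
    lifted_cap: float = LARGE_BOUND,
) -> CompensationReport:
    """Lift nutrient uptake caps set by set and score recovery by RMSE.

    The baseline (nothing lifted) is always included.  For every nutrient
    set, the member exchanges' caps are replaced by ``lifted_cap`` and the
    intensity sweep re-run; the RMSE of the resulting ATP curve against the
    control reference quantifies the remaining deficit.  Nutrients whose
    exchange is absent from the network are ignored, so such a scan equals
    the baseline.
    """
    baseline = run_intensity_sweep(
        network, scenarios, uptake_caps, o2_exchange, frozenset(), lifted_cap
    )
    control = {float(k): float(v) for k, v in control_reference.items()}
    rmse_by_scan = {frozenset(): rmse(baseline.atp_by_intensity, control)}
    scans: list[SweepResult] = []
    for nutrient_set in nutrient_sets:
        lifted = frozenset(nutrient_set)
        sweep = run_intensity_sweep(
            network, scenarios, uptake_caps, o2_exchange, lifted, lifted_cap
        )
        scans.append(sweep)
        rmse_by_scan[lifted] = rmse(sweep.atp_by_intensity, control)
    return CompensationReport(baseline, scans, rmse_by_scan, control)


def variability_report(
    network: MetabolicNetwork,
    scenarios: Sequence[IntensityScenario],
    reactions: Sequence[str],
    uptake_caps: Mapping,
    o2_exchange: str,
    fraction_of_optimum: float = 1.0,
    large_bound: float = LARGE_BOUND,
) -> dict[float, FluxRange]:
    """FVA ranges for selected enzymes at each intensity's ATP optimum.

    Uses the same per-intensity constraint setup as
    :func:`run_intensity_sweep` (O2 capped, fuel caps applied, ATP demand
    maximised); a zero-width range means the enzyme's flux is fully
    determined at the optimum — no metabolic flexibility remains.
    """
    for rid in reactions:
        if not network.has_reaction(rid):
            raise KeyError(f"unknown reaction id {rid!r}")
    out: dict[float, FluxRange] = {}
    for scen in scenarios:
        caps = _caps_for(uptake_caps, scen.percent_vo2max)
        net = network.set_bounds(o2_exchange, scen.o2_flux, 0.0)
        net = net.set_bounds(network.objective_reaction_id, 0.0, scen.atp_flux)
        for ex, cap in caps.items():
            if network.has_reaction(ex):
                net = net.set_bounds(ex, -abs(cap), 0.0)
        out[scen.percent_vo2max] = fva(
            net, fraction_of_optimum=fraction_of_optimum, reactions=list(reactions)
        )
    return out
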