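"""Inference of glucose / fatty-acid uptake fluxes from O2-ATP constraints.

At each exercise intensity the O2 uptake and ATP output of a muscle cell are
fixed from experimental measurements, but the nutrient uptakes that realise
them are unknown.  They are recovered by a variability-guided sweep: FVA
gives the maximal glucose uptake magnitude compatible with the fixed O2/ATP
pair; the glucose uptake bound is then decreased stepwise (fatty-acid uptake
rises in compensation, as ATP production must be maintained) until the ATP
share contributed by carbohydrate oxidation matches the literature target
proportion for that intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    FluxDistribution,
    InfeasibleProblemError,
    MetabolicNetwork,
    fba,
    fva,
)

__all__ = [
    "IntensityScenario",
    "FittedUptakes",
    "UnreachableProportionError",
    "fit_uptakes",
    "fit_all_intensities",
    "read_scenarios",
    "write_scenarios",
    "uptakes_table",
]

DEFAULT_STEP = 0.01  # μmol·gDW⁻¹·min⁻¹
DEFAULT_SHARE_TOLERANCE = 0.02


@dataclass(frozen=True)
class IntensityScenario:
    """One exercise intensity: fixed O2/ATP fluxes plus target fuel shares.

    ``o2_flux`` is the fixed (negative) O2 exchange flux, ``atp_flux`` the
    fixed (positive) ATP demand flux, both μmol·gDW⁻¹·min⁻¹;
    ``target_cho_share`` and ``target_betaox_share`` partition ATP
    production between carbohydrate oxidation and β-oxidation and must sum
    to 1.
    """

    percent_vo2max: float
    o2_flux: float
    atp_flux: float
    target_cho_share: float
    target_betaox_share: float

    def __post_init__(self):
        if self.o2_flux >= 0:
            raise ValueError("o2_flux must be negative (uptake)")
        if self.atp_flux <= 0:
            raise ValueError("atp_flux must be positive")
        if not (0 <= self.target_cho_share <= 1 and 0 <= self.target_betaox_share <= 1):
            raise ValueError("target shares must lie in [0, 1]")
        if abs(self.target_cho_share + self.target_betaox_share - 1.0) > 1e-9:
            raise ValueError("target shares must sum to 1")


@dataclass
class FittedUptakes:
    """Result of the glucose-sweep fit for one intensity."""

    glucose_uptake: float  # <= 0
    fa_uptake: float  # <= 0
    achieved_cho_share: float
    solution: FluxDistribution
    search_trace: list[tuple[float, float]] = field(default_factory=list)
    scenario: IntensityScenario | None = None


class UnreachableProportionError(RuntimeError):
    """No glucose bound along the sweep achieved the target share; carries
    the full (bound, achieved share) trace for diagnosis."""

    def __init__(self, message: str, trace: list[tuple[float, float]]):
        super().__init__(message)
        self.trace = trace


def _cho_share(sol: FluxDistribution, glucose_exchange: str, fa_exchange: str,
               fuel_yields: Mapping[str, float]) -> float:
    g = abs(min(sol.fluxes.get(glucose_exchange, 0.0), 0.0))
    f = abs(min(sol.fluxes.get(fa_exchange, 0.0), 0.0))
    num = fuel_yields[glucose_exchange] * g
    den = num + fuel_yields[fa_exchange] * f
    if den == 0:
        return float("nan")
    return num / den


def fit_uptakes(
    network: MetabolicNetwork,
    scenario: IntensityScenario,
    glucose_exchange: str,
    fa_exchange: str,
    o2_exchange: str,
    fuel_yields: Mapping[str, float],
    step: float = DEFAULT_STEP,
    share_tolerance: float = DEFAULT_SHARE_TOLERANCE,
    fix_atp: str = "equality",
) -> FittedUptakes:
    """Fit glucose and fatty-acid uptakes for one intensity scenario.

    Procedure: (1) fix the O2 exchange at ``scenario.o2_flux`` and the ATP
    demand at ``scenario.atp_flux`` (as an equality by default, or a lower
    bound with ``fix_atp='lower'`` for sensitivity checks); (2) find the
    maximal glucose uptake magnitude by FVA; (3) sweep the glucose lower
    bound from that extreme towards zero in increments of ``step``, each
    time solving a parsimonious FBA and computing the carbohydrate share of
    ATP production as ``Y_glc·|v_glc| / (Y_glc·|v_glc| + Y_fa·|v_fa|)`` with
    the provided single-fuel ATP yields; (4) return at the first bound whose
    achieved share is within ``share_tolerance`` of the target.  The
    fatty-acid uptake is read off the same parsimonious solution, making the
    returned pair unique.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if fix_atp not in ("equality", "lower"):
        raise ValueError("fix_atp must be 'equality' or 'lower'")
    for rid in (glucose_exchange, fa_exchange, o2_exchange):
        if not network.has_reaction(rid):
            raise KeyError(f"exchange reaction {rid!r} not in network")

    obj = network.objective_reaction_id
    net = network.set_bounds(o2_exchange, scenario.o2_flux, scenario.o2_flux)
    atp_ub = scenario.atp_flux if fix_atp == "equality" else network.reaction(obj).upper_bound
    net = net.set_bounds(obj, scenario.atp_flux, atp_ub)

    base = fba(net, parsimonious=False)
    if not base.optimal:
        raise InfeasibleProblemError(
            f"scenario at {scenario.percent_vo2max}% VO2max is infeasible "
            f"(O2 {scenario.o2_flux}, ATP {scenario.atp_flux})",
            context=scenario,
        )

    g_range = fva(net, reactions=[glucose_exchange]).ranges[glucose_exchange]
    g_max = g_range[0]  # most negative = maximal uptake

    trace: list[tuple[float, float]] = []
    g_bounds = np.arange(g_max, 0.0 + 0.5 * step, step)
    if g_bounds.size == 0 or g_bounds[-1] < 0.0:
        g_bounds = np.append(g_bounds, 0.0)
    glc_ub = min(network.reaction(glucose_exchange).upper_bound, 0.0)
    for g_lb in g_bounds:
        g_lb = min(float(g_lb), 0.0)
        candidate = net.set_bounds(glucose_exchange, g_lb, glc_ub)
        sol = fba(candidate)
        if not sol.optimal:
            trace.append((g_lb, float("nan")))
            continue
        share = _cho_share(sol, glucose_exchange, fa_exchange, fuel_yields)
        trace.append((g_lb, share))
        if np.isfinite(share) and abs(share - scenario.target_cho_share) <= share_tolerance:
            return FittedUptakes(
                glucose_uptake=float(sol.fluxes[glucose_exchange]),
                fa_uptake=float(sol.fluxes[fa_exchange]),
                achieved_cho_share=float(share),
                solution=sol,
                search_trace=trace,
                scenario=scenario,
            )
    raise UnreachableProportionError(
        f"no glucose bound in [{g_max:.4g}, 0] reaches carbohydrate share "
        f"{scenario.target_cho_share:.3f} ± {share_tolerance} at "
        f"{scenario.percent_vo2max}% VO2max",
        trace,
    )


def fit_all_intensities(
    network: MetabolicNetwork,
    scenarios: Sequence[IntensityScenario],
    glucose_exchange: str,
    fa_exchange: str,
    o2_exchange: str,
    fuel_yields: Mapping[str, float],
    step: float = DEFAULT_STEP,
    share_tolerance: float = DEFAULT_SHARE_TOLERANCE,
) -> tuple[dict[float, FittedUptakes], dict[float, Exception]]:
    """Fit every intensity; per-scenario failures are collected, not raised."""
    labels = [s.percent_vo2max for s in scenarios]
    if len(set(labels)) != len(labels):
        raise ValueError("scenario intensities must be distinct")
    results: dict[float, FittedUptakes] = {}
    failures: dict[float, Exception] = {}
    for scen in scenarios:
        try:
            results[scen.percent_vo2max] = fit_uptakes(
                network, scen, glucose_exchange, fa_exchange, o2_exchange,
                fuel_yields, step=step, share_tolerance=share_tolerance,
            )
        except (InfeasibleProblemError, UnreachableProportionError) as exc:
            failures[scen.percent_vo2max] = exc
    return results, failures


# -- tabular I/O -------------------------------------------------------------

SCENARIO_COLUMNS = ["percent_vo2max", "o2_flux", "atp_flux", "cho_share", "betaox_share"]


def read_scenarios(path) -> list[IntensityScenario]:
    """Read intensity scenarios from TSV (columns: percent_vo2max, o2_flux,
    atp_flux, cho_share, betaox_share)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(SCENARIO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"scenario table missing columns: {sorted(missing)}")
    return [
        IntensityScenario(
            percent_vo2max=float(r.percent_vo2max),
            o2_flux=float(r.o2_flux),
            atp_flux=float(r.atp_flux),
            target_cho_share=float(r.cho_share),
            target_betaox_share=float(r.betaox_share),
        )
        for r in df.itertuples()
    ]


def write_scenarios(scenarios: Sequence[IntensityScenario], path) -> None:
    df = pd.DataFrame(
        [
            {
                "percent_vo2max": s.percent_vo2max,
                "o2_flux": s.o2_flux,
                "atp_flux": s.atp_flux,
                "cho_share": s.target_cho_share,
                "betaox_share": s.target_betaox_share,
            }
            for s in scenarios
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def uptakes_table(results: Mapping[float, FittedUptakes]) -> pd.DataFrame:
    """Fitted uptakes as a tidy table (one row per intensity)."""
    rows = []
    for pct in sorted(results):
        fit = results[pct]
        rows.append(
            {
                "percent_vo2max": pct,
                "o2_flux": fit.scenario.o2_flux if fit.scenario else float("nan"),
                "atp_flux": fit.scenario.atp_flux if fit.scenario else float("nan"),
                "glucose_uptake": fit.glucose_uptake,
                "fa_uptake": fit.fa_uptake,
                "achieved_cho_share": fit.achieved_cho_share,
            }
        )
    return pd.DataFrame(rows)
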