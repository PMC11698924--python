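"""Model/Results facade tying the pipeline stages together.

:class:`MuscleEnergyModel` is built from a metabolic network plus a set of
intensity scenarios; its :meth:`~MuscleEnergyModel.fit` runs the uptake
inference for every intensity and returns a :class:`MuscleEnergyResults`
carrying the fitted uptakes, the control ATP curve, diagnostics and a
``summary()`` table.  Disease-model construction and nutrient-compensation
scans hang off the results object, since both consume the fitted control
state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import compensation as _comp
from . import disease as _dis
from . import fitting as _fit
from . import pathways as _pw
from .core import LARGE_BOUND, MetabolicNetwork

__all__ = ["MuscleEnergyModel", "MuscleEnergyResults"]


class MuscleEnergyModel:
    """Muscle energy metabolism under graded exercise demand.

    Parameters
    ----------
    network
        The stoichiometric network; its objective reaction is the ATP demand.
    scenarios
        One :class:`~myoflux.fitting.IntensityScenario` per exercise
        intensity (fixed O2/ATP fluxes plus target fuel shares).
    glucose_exchange, fa_exchange, o2_exchange
        Ids of the relevant exchange reactions.
    fuel_yields
        Maximal ATP per unit uptake for the two fitted fuels; probed by
        single-fuel FBA when omitted.
    step, share_tolerance
        Sweep increment (μmol·gDW⁻¹·min⁻¹) and accepted deviation of the
        achieved carbohydrate share from its target.
    """

    def __init__(
        self,
        network: MetabolicNetwork,
        scenarios: Sequence[_fit.IntensityScenario],
        glucose_exchange: str,
        fa_exchange: str,
        o2_exchange: str,
        fuel_yields: Mapping[str, float] | None = None,
        step: float = _fit.DEFAULT_STEP,
        share_tolerance: float = _fit.DEFAULT_SHARE_TOLERANCE,
    ):
        self.network = network
        self.scenarios = list(scenarios)
        self.glucose_exchange = glucose_exchange
        self.fa_exchange = fa_exchange
        self.o2_exchange = o2_exchange
        self.step = step
        self.share_tolerance = share_tolerance
        if fuel_yields is None:
            fuel_yields = _pw.yield_weights_by_probe(
                network, [glucose_exchange, fa_exchange], o2_exchange
            )
        self.fuel_yields = dict(fuel_yields)

    @classmethod
    def from_files(
        cls,
        model_path,
        scenario_path,
        glucose_exchange: str,
        fa_exchange: str,
        o2_exchange: str,
        model_format: str = "native_json",
        **kwargs,
    ) -> "MuscleEnergyModel":
        from .io import read_model

        network = read_model(model_path, format=model_format)
        scenarios = _fit.read_scenarios(scenario_path)
        return cls(network, scenarios, glucose_exchange, fa_exchange, o2_exchange, **kwargs)

    def fit(self) -> "MuscleEnergyResults":
        """Fit nutrient uptakes for every intensity scenario."""
        results, failures = _fit.fit_all_intensities(
            self.network,
            self.scenarios,
            self.glucose_exchange,
            self.fa_exchange,
            self.o2_exchange,
            self.fuel_yields,
            step=self.step,
            share_tolerance=self.share_tolerance,
        )
        return MuscleEnergyResults(self, results, failures)


@dataclass
class MuscleEnergyResults:
    """Fitted control state: per-intensity uptakes, solutions and diagnostics."""

    model: MuscleEnergyModel
    fits: dict[float, _fit.FittedUptakes]
    failures: dict[float, Exception] = field(default_factory=dict)

    # -- views ---------------------------------------------------------------
    @property
    def params(self) -> pd.DataFrame:
        """Fitted uptakes per intensity as a tidy table."""
        return _fit.uptakes_table(self.fits)

    def control_atp_curve(self) -> dict[float, float]:
        return {pct: fit.scenario.atp_flux for pct, fit in self.fits.items()}

    def control_caps(self) -> dict[float, dict[str, float]]:
        """Per-intensity uptake-cap magnitudes implied by the fit (glucose and
        fatty acid at their fitted values, other fuels at their network bounds)."""
        caps: dict[float, dict[str, float]] = {}
        for pct, fit in self.fits.items():
            caps[pct] = {
                self.model.glucose_exchange: abs(fit.glucose_uptake),
                self.model.fa_exchange: abs(fit.fa_uptake),
            }
        return caps

    def control_solutions(self):
        return {pct: fit.solution for pct, fit in self.fits.items()}

    # -- downstream stages ----------------------------------------------------
    def build_disease_model(
        self,
        records: Sequence[_dis.RegulationRecord],
        warning_cap_factor: float = 1.0,
        scope: str = "global",
    ):
        """Cap regulated enzymes at factor × control-maximal flux.

        Returns ``(disease_network, disease_bounds, unmatched_records)``.
        """
        profile = _dis.control_max_profile(self.control_solutions(), scope=scope)
        if scope == "per_intensity":
            raise NotImplementedError(
                "per-intensity scope requires building one network per intensity; "
                "use disease.control_max_profile directly"
            )
        return _dis.apply_disease_constraints(
            self.model.network, profile, records, warning_cap_factor
        )

    def compensation_scan(
        self,
        disease_network: MetabolicNetwork,
        nutrient_sets: Sequence[frozenset[str] | set[str]],
        lifted_cap: float = LARGE_BOUND,
    ) -> _comp.CompensationReport:
        """Lift nutrient uptake caps on the disease network and score ATP recovery."""
        return _comp.lift_bounds_scan(
            disease_network,
            self.model.scenarios,
            self.control_caps(),
            self.model.o2_exchange,
            nutrient_sets,
            self.control_atp_curve(),
            lifted_cap=lifted_cap,
        )

    def summary(self) -> str:
        """Human-readable fit report."""
        lines = [
            "Muscle energy metabolism — uptake fit",
            "=" * 54,
            f"network: {self.model.network.name or 'unnamed'} "
            f"({len(self.model.network.reactions)} reactions)",
            f"fuel yields (ATP per unit uptake): "
            + ", ".join(f"{k}={v:.3g}" for k, v in self.model.fuel_yields.items()),
            f"sweep step: {self.model.step} μmol·gDW⁻¹·min⁻¹; "
            f"share tolerance: {self.model.share_tolerance}",
            "",
            self.params.to_string(index=False, float_format=lambda x: f"{x:.4g}"),
        ]
        if self.failures:
            lines.append("")
            lines.append("failed intensities:")
            for pct, exc in sorted(self.failures.items()):
                lines.append(f"  {pct}% VO2max: {exc}")
        return "\n".join(lines)
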