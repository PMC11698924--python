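"""Per-pathway flux accounting and ATP-contribution shares.

Two share semantics are exposed because descriptive plots and fitting
criteria need different things:

* ``representative_flux`` — each pathway is summarised by the absolute flux
  through one or a few representative enzymatic reactions (e.g.
  phosphoglycerate mutase for glycolysis, acetyl-CoA acyltransferase for
  β-oxidation); shares are those fluxes normalised to sum to one.
* ``yield_weighted_uptake`` — each fuel's contribution is its uptake
  magnitude weighted by its maximal ATP yield per unit; shares then
  approximate the fraction of ATP production attributable to each fuel and
  are the quantity compared against literature pathway percentages during
  uptake fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core import FluxDistribution, MetabolicNetwork, fba

__all__ = [
    "PathwayDefinition",
    "PathwayShares",
    "pathway_fluxes",
    "pathway_shares",
    "yield_weights_by_probe",
]

PATHWAY_NAMES = ("glycolysis", "beta_oxidation", "ketone", "amino_acid", "glutamate", "cho_total")


@dataclass(frozen=True)
class PathwayDefinition:
    """How one pathway is measured from a flux distribution."""

    name: str
    representative_reaction_ids: tuple[str, ...]
    atp_yield_weight: float = 1.0
    mode: str = "representative_flux"

    def __post_init__(self):
        if not self.representative_reaction_ids:
            raise ValueError(f"pathway {self.name!r}: needs at least one representative reaction")
        if self.mode not in ("representative_flux", "yield_weighted_uptake"):
            raise ValueError(f"pathway {self.name!r}: unknown mode {self.mode!r}")
        if self.mode == "yield_weighted_uptake" and not self.atp_yield_weight > 0:
            raise ValueError(f"pathway {self.name!r}: yield weight must be > 0")
        if self.atp_yield_weight < 0:
            raise ValueError(f"pathway {self.name!r}: negative yield weight")
        object.__setattr__(
            self, "representative_reaction_ids", tuple(self.representative_reaction_ids)
        )


@dataclass
class PathwayShares:
    """Normalised pathway shares plus the absolute fluxes they came from.

    ``all_zero`` flags the degenerate case where every pathway flux vanishes
    (shares are then all zero rather than NaN)."""

    shares: dict[str, float]
    absolute: dict[str, float]
    all_zero: bool = False


def pathway_fluxes(
    distribution: FluxDistribution, definitions: Sequence[PathwayDefinition]
) -> dict[str, float]:
    """Absolute value of the summed representative fluxes, per pathway."""
    out: dict[str, float] = {}
    for d in definitions:
        total = 0.0
        for rid in d.representative_reaction_ids:
            if rid not in distribution.fluxes:
                raise KeyError(
                    f"pathway {d.name!r}: reaction {rid!r} absent from the flux distribution"
                )
            total += distribution.fluxes[rid]
        out[d.name] = abs(total)
    return out


def pathway_shares(
    distribution: FluxDistribution,
    definitions: Sequence[PathwayDefinition],
    mode: str = "representative_flux",
) -> PathwayShares:
    """Normalised pathway contributions under either share semantics."""
    if mode not in ("representative_flux", "yield_weighted_uptake"):
        raise ValueError(f"unknown mode {mode!r}")
    absolute = pathway_fluxes(distribution, definitions)
    if mode == "yield_weighted_uptake":
        weighted = {d.name: d.atp_yield_weight * absolute[d.name] for d in definitions}
    else:
        weighted = dict(absolute)
    total = sum(weighted.values())
    if total <= 0:
        return PathwayShares(
            shares={k: 0.0 for k in weighted}, absolute=absolute, all_zero=True
        )
    return PathwayShares(
        shares={k: v / total for k, v in weighted.items()},
        absolute=absolute,
        all_zero=False,
    )


def yield_weights_by_probe(
    network: MetabolicNetwork,
    fuel_exchanges: Sequence[str],
    o2_exchange: str,
    probe_cap: float = 1.0,
    large_bound: float = 1000.0,
) -> dict[str, float]:
    """Maximal ATP per unit of each fuel, measured by single-fuel FBA probes.

    For each fuel exchange, every other fuel uptake is closed, the probed
    uptake is capped at ``probe_cap``, O2 left unconstrained, and the ATP
    optimum recorded; the optimum divided by the cap is the fuel's ATP-yield
    weight.  This is how yield weights are derived for networks whose
    stoichiometry has no closed form.
    """
    weights: dict[str, float] = {}
    for probe in fuel_exchanges:
        net = network.set_bounds(o2_exchange, -large_bound, 0.0)
        for other in fuel_exchanges:
            if other == probe:
                net = net.set_bounds(other, -probe_cap, 0.0)
            else:
                net = net.set_bounds(other, 0.0, 0.0)
        sol = fba(net)
        if not sol.optimal:
            raise RuntimeError(f"yield probe for {probe!r} did not solve: {sol.status}")
        weights[probe] = sol.objective_value / probe_cap
    return weights
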