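"""Disease-constrained model construction from published enzyme regulations.

Published alterations of enzyme expression or activity (here: calpainopathy,
the CAPN3-deficient limb-girdle muscular dystrophy) are converted into
multiplicative correction factors:

* an in-vitro activity change of ``p`` percent → factor ``1 + p/100``
  (measured activities are taken as maxima);
* an expression fold-change ``F`` → factor ``F`` (maximal enzymatic activity
  is assumed proportional to total gene expression);
* a qualitative warning (e.g. inconsistent reports of mitochondrial
  dysfunction) → a configurable cap factor, 1.0 by default, i.e. the enzyme
  is held at its healthy maximum.

Each regulated reaction's upper flux bound becomes
``factor × (maximal control flux)``, where the control maximum is taken over
the FBA solutions of all exercise intensities (``global`` scope) or kept per
intensity.  Bounds are caps, not fixed values: enzyme activity may vary
below them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .core import FluxDistribution, MetabolicNetwork

__all__ = [
    "RegulationRecord",
    "DiseaseBound",
    "correction_factor",
    "control_max_profile",
    "apply_disease_constraints",
    "read_regulations",
    "write_regulations",
]

SOURCES = ("rnaseq", "activity", "qualitative_warning")


@dataclass(frozen=True)
class RegulationRecord:
    """One disease-induced enzymatic alteration.

    ``magnitude`` is a percent change for ``activity`` records, a
    fold-change for ``rnaseq`` records, and ignored (may be NaN) for
    ``qualitative_warning`` records.
    """

    reaction_id: str
    source: str
    magnitude: float = float("nan")
    citation_tag: str = ""

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValueError(f"unknown regulation source {self.source!r}")
        if self.source == "activity" and not self.magnitude > -100:
            raise ValueError(
                f"{self.reaction_id}: activity percent change must exceed -100, "
                f"got {self.magnitude}"
            )
        if self.source == "rnaseq" and not self.magnitude > 0:
            raise ValueError(
                f"{self.reaction_id}: expression fold-change must be positive, "
                f"got {self.magnitude}"
            )


@dataclass(frozen=True)
class DiseaseBound:
    """One derived flux cap: factor × maximal control flux."""

    reaction_id: str
    control_max_flux: float
    correction_factor: float
    disease_upper_bound: float
    scope: str = "global"


def correction_factor(record: RegulationRecord, warning_cap_factor: float = 1.0) -> float:
    """Multiplicative factor applied to the control maximal flux."""
    if record.source == "activity":
        factor = 1.0 + record.magnitude / 100.0
    elif record.source == "rnaseq":
        factor = float(record.magnitude)
    else:  # qualitative_warning
        factor = float(warning_cap_factor)
    if not factor > 0:
        raise ValueError(
            f"{record.reaction_id}: non-positive correction factor {factor}"
        )
    return factor


def control_max_profile(
    solutions: Mapping[float, FluxDistribution], scope: str = "global"
) -> dict[str, float] | dict[float, dict[str, float]]:
    """Maximal absolute control flux per reaction across intensity solutions.

    ``solutions`` maps intensity label → optimal control FluxDistribution
    (one per exercise intensity, under the fitted nutrient uptakes).  With
    ``scope='global'`` the result maps reaction id → max |flux| over all
    intensities; with ``scope='per_intensity'`` the per-intensity profiles
    are kept separate.
    """
    if not solutions:
        raise ValueError("no control solutions provided")
    for label, sol in solutions.items():
        if not sol.optimal:
            raise ValueError(f"control solution at intensity {label} is not optimal")
    if scope == "per_intensity":
        return {
            label: {rid: abs(v) for rid, v in sol.fluxes.items()}
            for label, sol in solutions.items()
        }
    if scope != "global":
        raise ValueError(f"unknown scope {scope!r}")
    profile: dict[str, float] = {}
    for sol in solutions.values():
        for rid, v in sol.fluxes.items():
            profile[rid] = max(profile.get(rid, 0.0), abs(v))
    return profile


def apply_disease_constraints(
    control_network: MetabolicNetwork,
    profile: Mapping[str, float],
    records: Sequence[RegulationRecord],
    warning_cap_factor: float = 1.0,
) -> tuple[MetabolicNetwork, list[DiseaseBound], list[RegulationRecord]]:
    """Build the disease network by capping regulated reactions.

    Each record's reaction gets upper bound ``factor × profile[reaction]``;
    reversible reactions are capped symmetrically in both directions, since
    activity data do not distinguish direction.  Records whose reaction id
    is absent from the network are returned in the third element (skipped
    with a warning, never fatal).  When several records target the same
    reaction, the most restrictive cap wins.
    """
    disease = control_network.copy()
    bounds: list[DiseaseBound] = []
    unmatched: list[RegulationRecord] = []
    caps: dict[str, float] = {}
    for rec in records:
        if not control_network.has_reaction(rec.reaction_id):
            unmatched.append(rec)
            continue
        factor = correction_factor(rec, warning_cap_factor)
        control_max = float(profile.get(rec.reaction_id, 0.0))
        cap = factor * control_max
        if rec.reaction_id in caps:
            cap = min(cap, caps[rec.reaction_id])
        caps[rec.reaction_id] = cap
        bounds.append(
            DiseaseBound(
                reaction_id=rec.reaction_id,
                control_max_flux=control_max,
                correction_factor=factor,
                disease_upper_bound=cap,
                scope="global",
            )
        )
    for rid, cap in caps.items():
        rxn = control_network.reaction(rid)
        lower = -cap if rxn.lower_bound < 0 else rxn.lower_bound
        lower = min(lower, cap)
        disease = disease.set_bounds(rid, lower, cap)
    return disease, bounds, unmatched


# -- TSV I/O ------------------------------------------------------------------

REGULATION_COLUMNS = ["reaction_id", "source", "magnitude", "citation_tag"]


def read_regulations(path) -> list[RegulationRecord]:
    """Read regulation records from TSV (columns: reaction_id, source,
    magnitude, citation_tag); round-trips losslessly with
    :func:`write_regulations`."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"citation_tag": str})
    missing = set(REGULATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"regulation table missing columns: {sorted(missing)}")
    records = []
    for r in df.itertuples():
        records.append(
            RegulationRecord(
                reaction_id=str(r.reaction_id),
                source=str(r.source),
                magnitude=float(r.magnitude),
                citation_tag="" if pd.isna(r.citation_tag) else str(r.citation_tag),
            )
        )
    return records


def write_regulations(records: Sequence[RegulationRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "reaction_id": r.reaction_id,
                "source": r.source,
                "magnitude": r.magnitude,
                "citation_tag": r.citation_tag,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)
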