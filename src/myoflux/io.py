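"""Model serialisation and species-presence curation.

Two on-disk formats are supported:

* ``native_json`` — the package's own schema, a UTF-8 JSON document with
  ``metabolites`` (id, name, compartment, is_boundary), ``reactions`` (id,
  name, stoichiometry map, lower_bound, upper_bound, ec_number, pathway_tag,
  is_exchange) and ``objective_reaction_id``.  Write∘read is the identity.
* ``sbml_fbc`` — import of community SBML Level 3 + FBC models (e.g. the
  MitoCore mitochondrial model) through COBRApy; bounds, EC annotations and
  compartments are preserved, and constructs the converter cannot represent
  raise explicitly rather than being dropped silently.

Curation adapts a model built for one species to another: each reaction's EC
number is looked up in a static presence table (a reproducible, offline
stand-in for live BRENDA queries) and a reaction is removed only when its EC
is recorded *absent* **and** the reaction appears on an explicit removal
whitelist — the data-encoded form of a manual literature check.  Reactions
with unknown or missing EC status are reported, never removed.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import MetabolicNetwork, Metabolite, Reaction, StructuralError

__all__ = [
    "PresenceTable",
    "CurationReport",
    "ModelParseError",
    "UnsupportedModelFeature",
    "read_model",
    "write_model",
    "read_presence_table",
    "write_presence_table",
    "curate_by_species",
]

_EC_PATTERN = re.compile(r"^[0-9]+\.(?:[0-9]+|-|n[0-9]*)\.(?:[0-9]+|-|n[0-9]*)\.(?:[0-9]+|-|n[0-9]*)$")

PRESENCE_STATUSES = ("present", "absent", "unknown")


class ModelParseError(ValueError):
    """A model file failed to parse; the message names the offending element."""


class UnsupportedModelFeature(ValueError):
    """The file uses a construct the importer cannot represent faithfully."""


@dataclass(frozen=True)
class PresenceTable:
    """EC number → present/absent/unknown for one species."""

    entries: Mapping[str, str]
    species_label: str = ""

    def __post_init__(self):
        clean = {}
        for ec, status in self.entries.items():
            ec = str(ec).strip()
            if not _EC_PATTERN.match(ec):
                raise ValueError(f"syntactically invalid EC number {ec!r}")
            if status not in PRESENCE_STATUSES:
                raise ValueError(f"EC {ec}: status {status!r} not in {PRESENCE_STATUSES}")
            clean[ec] = status
        object.__setattr__(self, "entries", clean)

    def status(self, ec: str | None) -> str | None:
        """Presence status for an EC number, or None when it has no entry."""
        if ec is None:
            return None
        return self.entries.get(ec)


@dataclass
class CurationReport:
    """Audit trail of a species-curation pass."""

    removed_reaction_ids: list[str] = field(default_factory=list)
    no_entry_ecs: list[str] = field(default_factory=list)
    absent_ecs: list[str] = field(default_factory=list)
    kept_despite_absent: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return len(self.removed_reaction_ids)

    def to_frame(self) -> pd.DataFrame:
        rows = [("removed", rid, "") for rid in self.removed_reaction_ids]
        rows += [("no_entry", ec, "") for ec in self.no_entry_ecs]
        rows += [("absent", ec, "") for ec in self.absent_ecs]
        rows += [("kept_despite_absent", rid, why) for rid, why in self.kept_despite_absent]
        return pd.DataFrame(rows, columns=["category", "identifier", "note"])


# -- native JSON --------------------------------------------------------------

def _network_to_dict(network: MetabolicNetwork) -> dict:
    return {
        "schema": "myoflux-network-1",
        "name": network.name,
        "objective_reaction_id": network.objective_reaction_id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "is_boundary": m.is_boundary,
            }
            for m in network.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "ec_number": r.ec_number,
                "pathway_tag": r.pathway_tag,
                "is_exchange": r.is_exchange,
            }
            for r in network.reactions
        ],
    }


def _network_from_dict(doc: dict, source: str = "<dict>") -> MetabolicNetwork:
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "cytosol"),
                is_boundary=bool(m.get("is_boundary", False)),
            )
            for m in doc["metabolites"]
        ]
        rxns = [
            Reaction(
                id=r["id"],
                stoichiometry={str(k): float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                name=r.get("name", ""),
                ec_number=r.get("ec_number"),
                pathway_tag=r.get("pathway_tag"),
                is_exchange=bool(r.get("is_exchange", False)),
            )
            for r in doc["reactions"]
        ]
        return MetabolicNetwork(
            mets, rxns, doc["objective_reaction_id"], name=doc.get("name", "")
        )
    except KeyError as exc:
        raise ModelParseError(f"{source}: missing required field {exc}") from exc
    except (TypeError, ValueError) as exc:
        raise ModelParseError(f"{source}: malformed element ({exc})") from exc


# -- SBML via COBRApy ---------------------------------------------------------

_COMPARTMENT_MAP = {
    "c": "cytosol", "cytosol": "cytosol", "cytoplasm": "cytosol",
    "m": "mitochondrion", "mitochondrion": "mitochondrion",
    "mitochondria": "mitochondrion", "mitochondrial matrix": "mitochondrion",
    "i": "mitochondrion", "mitochondrial intermembrane space": "mitochondrion",
    "e": "extracellular", "extracellular": "extracellular",
    "extracellular space": "extracellular", "s": "extracellular",
    "x": "cytosol", "b": "extracellular",
}


def _map_compartment(raw: str, names: Mapping[str, str]) -> str:
    for key in (raw, names.get(raw, "")):
        k = str(key).strip().lower()
        if k in _COMPARTMENT_MAP:
            return _COMPARTMENT_MAP[k]
    raise UnsupportedModelFeature(
        f"compartment {raw!r} cannot be mapped onto cytosol/mitochondrion/extracellular"
    )


def _read_sbml(path) -> MetabolicNetwork:
    try:
        import cobra
        from cobra.io import read_sbml_model
    except ImportError as exc:  # pragma: no cover - cobra is an install extra
        raise ImportError(
            "SBML import requires the 'cobra' package (install extra 'myoflux[sbml]')"
        ) from exc
    model = read_sbml_model(str(path))
    comp_names = dict(model.compartments)
    mets = [
        Metabolite(
            id=m.id,
            name=m.name or "",
            compartment=_map_compartment(m.compartment, comp_names),
            is_boundary=bool(getattr(m, "boundary_condition", False)),
        )
        for m in model.metabolites
    ]
    objective_ids = [r.id for r in model.reactions if r.objective_coefficient]
    if len(objective_ids) != 1:
        raise UnsupportedModelFeature(
            f"expected exactly one objective reaction, found {objective_ids}"
        )
    boundary = {m.id for m in mets if m.is_boundary}
    rxns = []
    for r in model.reactions:
        ec = r.annotation.get("ec-code")
        if isinstance(ec, list):
            ec = ec[0] if ec else None
        internal = [m.id for m in r.metabolites if m.id not in boundary]
        rxns.append(
            Reaction(
                id=r.id,
                stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                name=r.name or "",
                ec_number=ec,
                is_exchange=len(internal) == 1 and (r.boundary or len(r.metabolites) == 1),
            )
        )
    return MetabolicNetwork(mets, rxns, objective_ids[0], name=model.id or "")


def read_model(path, format: str = "native_json") -> MetabolicNetwork:
    """Read a metabolic network from ``native_json`` or ``sbml_fbc``."""
    if format == "native_json":
        try:
            with open(path, encoding="utf-8") as fh:
                doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelParseError(f"{path}: invalid JSON at line {exc.lineno}") from exc
        return _network_from_dict(doc, source=str(path))
    if format == "sbml_fbc":
        return _read_sbml(path)
    raise ValueError(f"unknown model format {format!r}")


def write_model(network: MetabolicNetwork, path, format: str = "native_json") -> None:
    """Write a network; ``native_json`` round-trips losslessly with read_model."""
    if format != "native_json":
        raise ValueError(f"writing format {format!r} is not supported (use native_json)")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_network_to_dict(network), fh, indent=1, sort_keys=False)
        fh.write("\n")


# -- presence table -----------------------------------------------------------

def read_presence_table(path, species_label: str = "") -> PresenceTable:
    """Read a TSV with columns ``ec`` and ``status``."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"ec", "status"} <= set(df.columns):
        raise ValueError(f"{path}: presence table needs columns 'ec' and 'status'")
    return PresenceTable(
        entries=dict(zip(df["ec"], df["status"])), species_label=species_label
    )


def write_presence_table(table: PresenceTable, path) -> None:
    pd.DataFrame(
        sorted(table.entries.items()), columns=["ec", "status"]
    ).to_csv(path, sep="\t", index=False)


# -- curation -----------------------------------------------------------------

def curate_by_species(
    network: MetabolicNetwork,
    table: PresenceTable,
    removal_whitelist: Sequence[str],
) -> tuple[MetabolicNetwork, CurationReport]:
    """Remove reactions absent in the target species, under whitelist control.

    A reaction is removed only when its EC status is ``absent`` *and* its id
    is whitelisted; absent-but-unlisted reactions are kept and reported with
    a justification.  Unknown or entry-less ECs are only reported.
    Whitelist entries that match no network reaction produce a warning in
    the report, not a failure.
    """
    report = CurationReport()
    known_ids = set(network.reaction_ids)
    for rid in removal_whitelist:
        if rid not in known_ids:
            report.warnings.append(f"whitelist entry {rid!r} not in network")
    whitelist = set(removal_whitelist) & known_ids

    to_remove: list[str] = []
    for rxn in network.reactions:
        status = table.status(rxn.ec_number)
        if rxn.ec_number is None or status is None:
            if rxn.ec_number is not None:
                report.no_entry_ecs.append(rxn.ec_number)
            continue
        if status == "absent":
            report.absent_ecs.append(rxn.ec_number)
            if rxn.id in whitelist:
                to_remove.append(rxn.id)
            else:
                report.kept_despite_absent.append(
                    (rxn.id, "absent in presence table but not whitelisted for removal")
                )
    report.removed_reaction_ids = to_remove
    curated = network.remove_reactions(to_remove) if to_remove else network.copy()
    return curated, report
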