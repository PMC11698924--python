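"""Packaged plain-text fixtures.

* ``scenarios_literature.tsv`` — the four graded-exercise constraint sets
  (fixed O2 uptake and ATP demand per % VO2max, with the literature
  carbohydrate/β-oxidation share targets) used to parameterise a murine
  muscle cell model.
* ``regulations_calpainopathy_synthetic.tsv`` — the calpainopathy regulation
  schema populated for the lumped mini-muscle network: the two published
  glycolytic activity changes (aldolase +133%, lactate dehydrogenase +287%)
  mapped onto their lumped reactions, one qualitative mitochondrial warning
  on the TCA lump, and 18 *synthetic* expression fold-changes standing in
  for the transcriptome-derived records (real per-gene fold-changes live in
  the source study's supplement and can be substituted by the user — the
  loader only cares about the schema).
* ``presence_murine_synthetic.tsv`` — a *synthetic* species-presence table
  (EC → present/absent/unknown) covering the mini-muscle EC numbers,
  standing in for offline BRENDA lookups.
"""

from __future__ import annotations

from importlib import resources

from .disease import RegulationRecord, read_regulations
from .fitting import IntensityScenario, read_scenarios
from .io import PresenceTable, read_presence_table

__all__ = [
    "fixture_path",
    "load_literature_scenarios",
    "load_synthetic_regulations",
    "load_synthetic_presence_table",
]


def fixture_path(name: str):
    """Filesystem path of a packaged fixture (context-manager-free; the
    package is installed unzipped)."""
    return resources.files("myoflux").joinpath("data", name)


def load_literature_scenarios() -> list[IntensityScenario]:
    return read_scenarios(fixture_path("scenarios_literature.tsv"))


def load_synthetic_regulations() -> list[RegulationRecord]:
    return read_regulations(fixture_path("regulations_calpainopathy_synthetic.tsv"))


def load_synthetic_presence_table() -> PresenceTable:
    return read_presence_table(
        fixture_path("presence_murine_synthetic.tsv"), species_label="murine-synthetic"
    )
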