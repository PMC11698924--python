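"""Self-contained lumped muscle-cell energy network with closed-form yields.

The "mini-muscle" network condenses the energy metabolism of a skeletal
muscle cell into one lumped reaction per pathway: glycolysis, reversible
lactate dehydrogenase, pyruvate dehydrogenase, β-oxidation of a
palmitate-like fatty acid, a lumped TCA cycle, electron transport at
configurable P/O ratios, ketone-body / amino-acid / glycerol entry points,
and exchange reactions for every substrate plus O2, lactate and CO2.  Every
internal metabolite is balanced by construction, so maximal ATP and O2
demands per unit substrate have closed forms (:func:`analytic_yields`) that
serve as exact oracles for the LP machinery.

This is a test scaffold with textbook stoichiometry and P/O ratios, not a
claim about murine physiology: with the defaults, one glucose yields 32 ATP
consuming 6 O2, one fatty acid 106 ATP consuming 23 O2, and anaerobic
glucose yields 2 ATP with 2 lactate exported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import LARGE_BOUND, MetabolicNetwork, Metabolite, Reaction
from .disease import RegulationRecord
from .fitting import IntensityScenario

__all__ = [
    "SUBSTRATES",
    "EXCHANGE_IDS",
    "DEFAULT_SEED",
    "MiniMuscleConfig",
    "GroundTruthScenario",
    "build_mini_muscle",
    "analytic_yields",
    "make_scenarios",
    "default_scenarios",
    "DEFAULT_DEMANDS",
    "sample_regulation_records",
]

SUBSTRATES = ("glucose", "fatty_acid", "ketone_body", "amino_acids", "glycerol")

#: Exchange reaction id per substrate / gas / by-product.
EXCHANGE_IDS = {
    "glucose": "EX_glc",
    "fatty_acid": "EX_fa",
    "ketone_body": "EX_kb",
    "amino_acids": "EX_aa",
    "glycerol": "EX_glyc",
    "o2": "EX_o2",
    "lactate": "EX_lac",
    "co2": "EX_co2",
}

#: Fixed default seed for every random generation step in this module.
DEFAULT_SEED = 20241209


@dataclass(frozen=True)
class MiniMuscleConfig:
    """Tunable stoichiometry of the lumped network.

    P/O ratios are ATP per reducing equivalent oxidised (per ½ O2):
    ``po_nadh`` for mitochondrial NADH (default 2.5), ``po_fadh2`` for FADH2
    (default 1.5) and ``cytosolic_nadh_yield`` for cytosolic NADH delivered
    through a shuttle (default 2.5, i.e. a lossless malate–aspartate-like
    shuttle).  ``default_uptake_caps`` are uptake magnitudes in
    μmol·gDW⁻¹·min⁻¹; minor fuels default to 0 so experiments enable them
    explicitly.
    """

    po_nadh: float = 2.5
    po_fadh2: float = 1.5
    cytosolic_nadh_yield: float = 2.5
    substrates: tuple[str, ...] = SUBSTRATES
    default_uptake_caps: Mapping[str, float] = field(
        default_factory=lambda: {
            "glucose": 5.0,
            "fatty_acid": 1.0,
            "ketone_body": 0.0,
            "amino_acids": 0.0,
            "glycerol": 0.0,
        }
    )
    large_bound: float = LARGE_BOUND

    def __post_init__(self):
        if min(self.po_nadh, self.po_fadh2, self.cytosolic_nadh_yield) <= 0:
            raise ValueError("P/O yields must be positive")
        unknown = set(self.substrates) - set(SUBSTRATES)
        if unknown:
            raise ValueError(f"unknown substrates: {sorted(unknown)}")
        if any(v < 0 for v in self.default_uptake_caps.values()):
            raise ValueError("uptake caps must be non-negative")

    def uptake_cap(self, substrate: str) -> float:
        return float(self.default_uptake_caps.get(substrate, 0.0))


@dataclass(frozen=True)
class GroundTruthScenario:
    """Known-truth uptakes behind a generated intensity scenario (uptake
    magnitudes, μmol·gDW⁻¹·min⁻¹)."""

    true_glucose_uptake: float
    true_fa_uptake: float
    implied_o2: float  # negative exchange flux
    implied_atp: float
    implied_cho_share: float


def _met(mid, compartment="cytosol"):
    return Metabolite(mid, compartment=compartment)


def build_mini_muscle(config: MiniMuscleConfig | None = None) -> MetabolicNetwork:
    """Assemble the lumped muscle network for a configuration.

    Substrates outside ``config.substrates`` are omitted entirely (their
    exchange and degradation reactions do not exist); substrates present but
    with a zero default cap exist with a closed uptake bound.
    """
    cfg = config or MiniMuscleConfig()
    big = cfg.large_bound

    mets = [
        _met("glc_c"),
        _met("pyr_c"),
        _met("lac_c"),
        _met("nadh_c"),
        _met("atp_c"),
        _met("accoa_m", "mitochondrion"),
        _met("nadh_m", "mitochondrion"),
        _met("fadh2_m", "mitochondrion"),
        _met("o2_c"),
        _met("co2_c"),
    ]
    sub_met = {
        "glucose": "glc_c",
        "fatty_acid": "fa_c",
        "ketone_body": "kb_c",
        "amino_acids": "aa_c",
        "glycerol": "glyc_c",
    }
    for s in cfg.substrates:
        if s != "glucose":
            mets.append(_met(sub_met[s]))

    rxns: list[Reaction] = []

    def add(rid, stoich, lb, ub, **kw):
        rxns.append(Reaction(rid, stoich, lb, ub, **kw))

    # Glycolysis lump: glucose -> 2 pyruvate + 2 ATP + 2 cytosolic NADH
    add(
        "GLYCOLYSIS",
        {"glc_c": -1, "pyr_c": 2, "atp_c": 2, "nadh_c": 2},
        0, big, name="glycolysis (phosphoglycerate mutase lump)",
        ec_number="5.4.2.11", pathway_tag="glycolysis",
    )
    # Reversible lactate dehydrogenase: pyruvate + NADH_c <-> lactate
    add(
        "LDH",
        {"pyr_c": -1, "nadh_c": -1, "lac_c": 1},
        -big, big, name="lactate dehydrogenase",
        ec_number="1.1.1.27", pathway_tag="glycolysis",
    )
    # Pyruvate dehydrogenase: pyruvate -> acetyl-CoA + NADH_m + CO2
    add(
        "PDH",
        {"pyr_c": -1, "accoa_m": 1, "nadh_m": 1, "co2_c": 1},
        0, big, name="pyruvate dehydrogenase",
        ec_number="1.2.4.1", pathway_tag="glycolysis",
    )
    # TCA lump per acetyl-CoA: 3 NADH + 1 FADH2 + 1 ATP-equivalent (GTP) + 2 CO2
    add(
        "TCA",
        {"accoa_m": -1, "nadh_m": 3, "fadh2_m": 1, "atp_c": 1, "co2_c": 2},
        0, big, name="TCA cycle (citrate synthase lump)",
        ec_number="2.3.3.1", pathway_tag="tca",
    )
    # Electron transport at configured P/O ratios
    add(
        "ETC_NADH",
        {"nadh_m": -1, "o2_c": -0.5, "atp_c": cfg.po_nadh},
        0, big, name="electron transport, NADH",
        ec_number="7.1.1.2", pathway_tag="oxphos",
    )
    add(
        "ETC_FADH2",
        {"fadh2_m": -1, "o2_c": -0.5, "atp_c": cfg.po_fadh2},
        0, big, name="electron transport, FADH2",
        ec_number="1.3.5.1", pathway_tag="oxphos",
    )
    # Cytosolic NADH oxidation via shuttle (lossless by default)
    add(
        "SHUTTLE_NADH",
        {"nadh_c": -1, "o2_c": -0.5, "atp_c": cfg.cytosolic_nadh_yield},
        0, big, name="cytosolic NADH shuttle + oxidation",
        pathway_tag="oxphos",
    )
    if "fatty_acid" in cfg.substrates:
        # β-oxidation of a palmitate-like C16 fatty acid, 2 ATP activation cost
        add(
            "BETA_OX",
            {"fa_c": -1, "atp_c": -2, "accoa_m": 8, "nadh_m": 7, "fadh2_m": 7},
            0, big, name="beta-oxidation (acetyl-CoA acyltransferase lump)",
            ec_number="2.3.1.16", pathway_tag="beta_oxidation",
        )
    if "ketone_body" in cfg.substrates:
        # 3-hydroxybutyrate -> 2 acetyl-CoA + NADH, one ATP-equivalent for activation
        add(
            "KETOLYSIS",
            {"kb_c": -1, "atp_c": -1, "accoa_m": 2, "nadh_m": 1},
            0, big, name="ketone body degradation (BDH lump)",
            ec_number="1.1.1.30", pathway_tag="ketone",
        )
    if "amino_acids" in cfg.substrates:
        # lumped ketogenic/glucogenic amino acid -> acetyl-CoA + NADH (N ignored)
        add(
            "AA_DEG",
            {"aa_c": -1, "accoa_m": 1, "nadh_m": 1, "co2_c": 1},
            0, big, name="amino acid degradation (BCAA transaminase lump)",
            ec_number="2.6.1.42", pathway_tag="amino_acid",
        )
    if "glycerol" in cfg.substrates:
        # glycerol -> pyruvate via G3P; net +1 ATP and one FADH2 (mito G3P shuttle)
        add(
            "GLYCEROL_ENTRY",
            {"glyc_c": -1, "pyr_c": 1, "fadh2_m": 1, "atp_c": 1},
            0, big, name="glycerol entry into lower glycolysis",
            ec_number="2.7.1.30", pathway_tag="glycolysis",
        )
    # ATP demand (objective): hydrolysis sink
    add("ATP_DEMAND", {"atp_c": -1}, 0, big, name="ATP demand", pathway_tag="other")

    # Exchanges: negative flux = uptake
    for s in cfg.substrates:
        add(
            EXCHANGE_IDS[s],
            {sub_met[s]: -1},
            -cfg.uptake_cap(s), 0.0,
            name=f"{s} exchange", pathway_tag="exchange", is_exchange=True,
        )
    add(EXCHANGE_IDS["o2"], {"o2_c": -1}, -big, 0.0,
        name="O2 exchange", pathway_tag="exchange", is_exchange=True)
    add(EXCHANGE_IDS["lactate"], {"lac_c": -1}, 0.0, big,
        name="lactate exchange", pathway_tag="exchange", is_exchange=True)
    add(EXCHANGE_IDS["co2"], {"co2_c": -1}, 0.0, big,
        name="CO2 exchange", pathway_tag="exchange", is_exchange=True)

    return MetabolicNetwork(mets, rxns, "ATP_DEMAND", name="mini-muscle")


def analytic_yields(config: MiniMuscleConfig, substrate: str) -> tuple[float, float]:
    """Closed-form (ATP per unit, O2 per unit) for aerobic single-substrate use.

    These follow directly from the lumped coefficients and are exact LP
    oracles: maximal ATP per unit substrate and the O2 consumed to reach it.
    """
    if substrate not in config.substrates:
        raise KeyError(f"substrate {substrate!r} not in configuration")
    pn, pf, pc = config.po_nadh, config.po_fadh2, config.cytosolic_nadh_yield
    accoa_atp = 3 * pn + pf + 1.0  # TCA NADH/FADH2/GTP fully oxidised
    accoa_o2 = 2.0  # 3 NADH + 1 FADH2 = 4 reducing equivalents x 0.5 O2
    if substrate == "glucose":
        atp = 2 + 2 * pc + 2 * (pn + accoa_atp)
        o2 = 2 * 0.5 + 2 * 0.5 + 2 * accoa_o2
    elif substrate == "fatty_acid":
        atp = -2 + 7 * pn + 7 * pf + 8 * accoa_atp
        o2 = 7 * 0.5 + 7 * 0.5 + 8 * accoa_o2
    elif substrate == "ketone_body":
        atp = -1 + pn + 2 * accoa_atp
        o2 = 0.5 + 2 * accoa_o2
    elif substrate == "amino_acids":
        atp = pn + accoa_atp
        o2 = 0.5 + accoa_o2
    elif substrate == "glycerol":
        atp = 1 + pf + pn + accoa_atp
        o2 = 0.5 + 0.5 + accoa_o2
    else:  # pragma: no cover - guarded above
        raise KeyError(substrate)
    return float(atp), float(o2)


def make_scenarios(
    config: MiniMuscleConfig,
    uptake_pairs: Sequence[tuple[float, float]],
    percent_labels: Sequence[float] | None = None,
) -> list[tuple[IntensityScenario, GroundTruthScenario]]:
    """Generate intensity scenarios from known-truth (glucose, fatty-acid) uptakes.

    Each pair of uptake magnitudes implies, through the analytic yields, the
    O2 and ATP fluxes and the carbohydrate share that an aerobic optimum
    must reproduce; those implied values become the scenario's fixed
    constraints and fitting targets.
    """
    y_glc, o_glc = analytic_yields(config, "glucose")
    y_fa, o_fa = analytic_yields(config, "fatty_acid")
    labels = list(percent_labels) if percent_labels is not None else None
    if labels is not None and len(labels) != len(uptake_pairs):
        raise ValueError("percent_labels length must match uptake_pairs")
    out = []
    for i, (g, f) in enumerate(uptake_pairs):
        if g < 0 or f < 0:
            raise ValueError("uptake magnitudes must be non-negative")
        if g == 0 and f == 0:
            raise ValueError("degenerate scenario: both uptakes are zero")
        atp = y_glc * g + y_fa * f
        o2 = o_glc * g + o_fa * f
        cho = (y_glc * g) / atp
        label = labels[i] if labels is not None else float(i + 1)
        scen = IntensityScenario(
            percent_vo2max=label,
            o2_flux=-o2,
            atp_flux=atp,
            target_cho_share=cho,
            target_betaox_share=1.0 - cho,
        )
        truth = GroundTruthScenario(g, f, -o2, atp, cho)
        out.append((scen, truth))
    return out


#: Default study conditions: exercise intensities (% VO2max) with their ATP
#: demand (μmol·gDW⁻¹·min⁻¹) and target carbohydrate share of ATP production.
DEFAULT_DEMANDS = (
    (25.0, 14.6, 0.40),
    (65.0, 36.52, 0.50),
    (85.0, 54.8, 0.80),
    (100.0, 75.0, 1.00),
)


def default_scenarios(
    config: MiniMuscleConfig | None = None,
    demands: Sequence[tuple[float, float, float]] = DEFAULT_DEMANDS,
) -> list[tuple[IntensityScenario, GroundTruthScenario]]:
    """Four graded-exercise scenarios with known ground-truth uptakes.

    Each demand triple (percent VO2max, ATP flux, carbohydrate share) is
    converted into the unique aerobic (glucose, fatty-acid) uptake pair that
    realises it under the network's analytic yields; O2 follows.  The default
    ATP demands and shares are the literature exercise-physiology values used
    throughout the package's worked examples.
    """
    cfg = config or MiniMuscleConfig()
    y_glc, _ = analytic_yields(cfg, "glucose")
    y_fa, _ = analytic_yields(cfg, "fatty_acid")
    pairs = [
        (share * atp / y_glc, (1.0 - share) * atp / y_fa)
        for _, atp, share in demands
    ]
    labels = [pct for pct, _, _ in demands]
    return make_scenarios(cfg, pairs, percent_labels=labels)


def sample_regulation_records(
    seed: int = DEFAULT_SEED,
    n: int = 18,
    factor_range: tuple[float, float] = (0.3, 2.5),
    reaction_ids: Sequence[str] | None = None,
    sources: tuple[str, ...] = ("rnaseq", "activity"),
) -> list[RegulationRecord]:
    """Draw reproducible synthetic disease-regulation records.

    Records mix expression fold-changes (``rnaseq``) and activity percent
    changes (``activity``) with correction factors inside ``factor_range``;
    both up- and down-regulations are drawn whenever the range straddles 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = factor_range
    if not (0 < lo <= hi):
        raise ValueError("factor_range must satisfy 0 < low <= high")
    rng = np.random.default_rng(seed)
    pool = list(reaction_ids) if reaction_ids is not None else [
        "GLYCOLYSIS", "LDH", "PDH", "TCA", "ETC_NADH", "ETC_FADH2",
        "BETA_OX", "KETOLYSIS", "AA_DEG",
    ]
    records = []
    for i in range(n):
        rid = pool[int(rng.integers(len(pool)))]
        if lo < 1.0 < hi:
            # alternate halves of the range so up/down both occur
            factor = float(rng.uniform(lo, 1.0)) if i % 2 else float(rng.uniform(1.0, hi))
        else:
            factor = float(rng.uniform(lo, hi))
        if "activity" in sources and "rnaseq" in sources:
            source = "activity" if i % 5 == 0 else "rnaseq"
        else:
            source = sources[0]
        magnitude = (factor - 1.0) * 100.0 if source == "activity" else factor
        records.append(
            RegulationRecord(
                reaction_id=rid,
                source=source,
                magnitude=magnitude,
                citation_tag=f"synthetic:{seed}:{i}",
            )
        )
    return records
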