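"""Configuration types for the perturbational blood-phenotyping pipeline.

All tunable parameters of the pipeline live in small dataclasses so that a
single YAML file can drive an end-to-end run.  Defaults follow the study
design the package models: a perturbational whole-blood cytometry screen
(four analyzer channels, axis-aligned gates), robust phenotype QC, a
covariate-adjusted GWAS with multi-trait LD clumping, clinical association
with Storey FDR, and clumping-and-thresholding polygenic scores evaluated
with delayed-entry Cox models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

#: Upper edge of the instrument's optical dynamic range (18-bit scale).
INSTRUMENT_MAX = 2 ** 18

CHANNELS = ("WDF", "WNR", "RET", "PLTF")


class ConfigurationError(ValueError):
    """Raised when a configuration value is outside its documented range."""


@dataclass(frozen=True)
class GateTemplate:
    """Gaussian anchor for one cytometry gate in (FSC, SSC, SFL) space.

    Parameters
    ----------
    name : str
        Gate label, e.g. ``"NE2"`` (evoked high-SSC/high-SFL neutrophils).
    channel : str
        Analyzer channel the gate lives in; one of WDF/WNR/RET/PLTF.
        Gates never span channels.
    mean : tuple of 3 floats
        Component mean (FSC, SSC, SFL) in instrument units.
    spread : tuple of 3 floats
        Diagonal Gaussian spread per axis; strictly positive.
    weights : dict
        Baseline mixture weight per condition id.
    """

    name: str
    channel: str
    mean: tuple[float, float, float]
    spread: tuple[float, float, float]
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ConfigurationError(
                f"unknown channel {self.channel!r}; expected one of {CHANNELS}"
            )
        if any(s <= 0 for s in self.spread):
            raise ConfigurationError(f"gate {self.name}: spreads must be > 0")


@dataclass(frozen=True)
class CausalEffect:
    """A genetic effect on a gate's mixture weight (log-scale shift per allele)."""

    variant: int
    condition: str
    gate: str
    effect_size: float  # in latent s.d. units per standardized allele dose


@dataclass(frozen=True)
class OutcomeEffect:
    """A latent-trait effect on a clinical outcome's hazard (log hazard ratio)."""

    latent: str
    outcome: str
    log_hr: float


@dataclass
class SimulationConfig:
    n_donors: int = 200
    n_variants: int = 500
    ld_block_size: int = 25
    ld_rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    conditions: list[str] = field(
        default_factory=lambda: ["baseline", "Pam3CSK4_19h", "LPS_18h"]
    )
    gate_templates: list[GateTemplate] = field(default_factory=list)
    causal_effects: list[CausalEffect] = field(default_factory=list)
    outcome_effects: list[OutcomeEffect] = field(default_factory=list)
    outcomes: list[str] = field(default_factory=lambda: ["T2D", "CKD", "HF"])
    events_per_sample: int = 2000
    genotype_missing_rate: float = 0.0
    #: s.d. of the per-donor environmental noise on each latent gate weight
    latent_noise_sd: float = 1.0
    #: disease prevalence feeding the "inflammatory tone" latent
    disease_prevalence: float = 0.2
    #: effect of disease status on the inflammatory-tone latent (s.d. units)
    tone_disease_shift: float = 1.0
    #: loading of the tone latent on every evoked (non-baseline) gate weight
    tone_loading: float = 0.3
    #: population means for simulated continuous labs
    lab_means: dict[str, float] = field(
        default_factory=lambda: {"eGFR": 90.0, "HbA1C": 5.6}
    )
    #: Weibull baseline hazard for disease onset: shape > 1 concentrates
    #: onsets late in life, as for chronic disease; shape = 1 is exponential
    onset_shape: float = 5.0
    onset_scale: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError(
                f"maf_range must lie strictly inside (0, 0.5], got {self.maf_range}"
            )
        if not (0 <= self.ld_rho < 1):
            raise ConfigurationError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        if self.n_donors < 2 or self.n_variants < 1:
            raise ConfigurationError("need n_donors >= 2 and n_variants >= 1")
        if not (0 <= self.genotype_missing_rate < 1):
            raise ConfigurationError("genotype_missing_rate must be in [0, 1)")
        for eff in self.outcome_effects:
            import math

            if not math.isfinite(eff.log_hr):
                raise ConfigurationError(
                    f"non-finite log hazard ratio for {eff.outcome}"
                )
        if not self.gate_templates:
            self.gate_templates = default_gate_templates(self.conditions)
        self._check_gates()

    def _check_gates(self) -> None:
        seen: set[tuple[str, str]] = set()
        for g in self.gate_templates:
            key = (g.channel, g.name)
            if key in seen:
                raise ConfigurationError(f"duplicate gate {g.name} in {g.channel}")
            seen.add(key)
        for cond in self.conditions:
            for ch in CHANNELS:
                tot = sum(
                    g.weights.get(cond, 0.0)
                    for g in self.gate_templates
                    if g.channel == ch
                )
                if tot > 0 and abs(tot - 1.0) > 1e-9:
                    raise ConfigurationError(
                        f"mixture weights for ({cond}, {ch}) sum to {tot}, not 1"
                    )


@dataclass
class QcParameters:
    """Phenotype QC thresholds.

    ``mad_multiplier`` is the univariate outlier threshold (cells beyond
    k MADs of the column median are masked); ``ica_mad_multiplier`` is the
    sample-level threshold on distances in the 2-D ICA projection;
    ``variance_threshold`` is the cumulative explained-variance level used
    to count effective independent traits per measurement block.
    """

    mad_multiplier: float = 4.0
    ica_mad_multiplier: float = 2.5
    variance_threshold: float = 0.90
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mad_multiplier <= 0 or self.ica_mad_multiplier <= 0:
            raise ConfigurationError("MAD multipliers must be > 0")
        if not (0 < self.variance_threshold <= 1):
            raise ConfigurationError("variance_threshold must be in (0, 1]")


@dataclass
class ScanConfig:
    """Variant QC and association-scan thresholds."""

    maf_floor: float = 0.05
    mac_floor: int = 10
    missingness_ceiling: float = 0.10
    hwe_p_floor: float = 1e-50
    kinship_ceiling: float = 0.177
    n_pcs: int = 10
    significance: float = 5e-8
    clump_r2: float = 0.50
    clump_kb: float = 250.0
    min_supporting_traits: int = 2
    #: if True, "independent hits" additionally requires distinct variants
    require_distinct_variants: bool = False


@dataclass
class PgsConfig:
    """Clumping-and-thresholding PGS construction parameters."""

    clump_p1: float = 0.5
    clump_r2: float = 0.5
    clump_kb: float = 100.0
    score_p: float = 0.1


@dataclass
class SurvivalConfig:
    instant_window: float = 1.0  # years
    min_events: int = 2
    quartile_probs: tuple[float, float, float] = (0.25, 0.5, 0.75)


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QcParameters = field(default_factory=QcParameters)
    scan: ScanConfig = field(default_factory=ScanConfig)
    pgs: PgsConfig = field(default_factory=PgsConfig)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))
    seed: int = 0


STAGE_ORDER = (
    "simulate",
    "gate",
    "qc",
    "scan",
    "clump",
    "clinical",
    "pgs",
    "survive",
    "meta",
    "ica",
)


def default_gate_templates(conditions: Sequence[str]) -> list[GateTemplate]:
    """Canonical gate set for the four analyzer channels.

    The layout mirrors the published channel structure — WBC differential
    gates in WDF, white-count/NRBC gates in WNR, red-cell and reticulocyte
    gates in RET, platelet gates in PLT-F — with component anchors spread
    over the 18-bit optical range.  The evoked neutrophil gate NE2 starts
    near zero weight at baseline and grows under stimulation, like the
    high-SSC/high-SFL population that appears only after perturbation.
    """
    base = float(INSTRUMENT_MAX)

    def mk(name, ch, fx, fy, fz, w_base, w_pert):
        mean = (fx * base, fy * base, fz * base)
        spread = (0.018 * base, 0.018 * base, 0.018 * base)
        weights = {}
        for c in conditions:
            weights[c] = w_base if c == "baseline" else w_pert
        return GateTemplate(name, ch, mean, spread, weights)

    wdf = [
        # name    fx    fy    fz    baseline  perturbed
        ("NE1", 0.30, 0.30, 0.30, 0.30, 0.25),
        ("NE2", 0.30, 0.70, 0.70, 0.00, 0.10),
        ("NE3", 0.55, 0.30, 0.55, 0.15, 0.15),
        ("MO", 0.55, 0.55, 0.30, 0.12, 0.12),
        ("MO2", 0.70, 0.70, 0.30, 0.03, 0.03),
        ("LY", 0.15, 0.15, 0.55, 0.25, 0.20),
        ("EO1", 0.70, 0.30, 0.15, 0.05, 0.05),
        ("EO2", 0.85, 0.45, 0.15, 0.02, 0.02),
        ("DEBRIS", 0.05, 0.05, 0.05, 0.08, 0.08),
    ]
    wnr = [
        ("WBC", 0.30, 0.30, 0.55, 0.55, 0.50),
        ("WBC1", 0.55, 0.30, 0.30, 0.15, 0.15),
        ("WBC2", 0.55, 0.55, 0.70, 0.10, 0.15),
        ("BASO", 0.30, 0.70, 0.30, 0.05, 0.05),
        ("NRBC", 0.15, 0.15, 0.15, 0.05, 0.05),
        ("GHOST", 0.05, 0.55, 0.05, 0.10, 0.10),
    ]
    ret = [
        ("RBC1", 0.30, 0.30, 0.15, 0.55, 0.50),
        ("RBC2", 0.55, 0.30, 0.30, 0.20, 0.20),
        ("RET1", 0.30, 0.55, 0.55, 0.15, 0.20),
        ("RET2", 0.55, 0.70, 0.70, 0.05, 0.05),
        ("UK1", 0.80, 0.15, 0.15, 0.05, 0.05),
    ]
    pltf = [
        ("PLT", 0.15, 0.15, 0.30, 0.80, 0.75),
        ("IPF", 0.30, 0.30, 0.60, 0.20, 0.25),
    ]
    out: list[GateTemplate] = []
    for name, fx, fy, fz, wb, wp in wdf:
        out.append(mk(name, "WDF", fx, fy, fz, wb, wp))
    for name, fx, fy, fz, wb, wp in wnr:
        out.append(mk(name, "WNR", fx, fy, fz, wb, wp))
    for name, fx, fy, fz, wb, wp in ret:
        out.append(mk(name, "RET", fx, fy, fz, wb, wp))
    for name, fx, fy, fz, wb, wp in pltf:
        out.append(mk(name, "PLTF", fx, fy, fz, wb, wp))
    return out


# ---------------------------------------------------------------------------
# YAML round trip


def load_config(path: str) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    sim_raw = dict(raw.get("simulation", {}))
    gates = [
        GateTemplate(
            name=g["name"],
            channel=g["channel"],
            mean=tuple(g["mean"]),
            spread=tuple(g["spread"]),
            weights=dict(g["weights"]),
        )
        for g in sim_raw.pop("gate_templates", [])
    ]
    causal = [CausalEffect(**c) for c in sim_raw.pop("causal_effects", [])]
    outcome = [OutcomeEffect(**o) for o in sim_raw.pop("outcome_effects", [])]
    if "maf_range" in sim_raw:
        sim_raw["maf_range"] = tuple(sim_raw["maf_range"])
    sim = SimulationConfig(
        gate_templates=gates, causal_effects=causal, outcome_effects=outcome, **sim_raw
    )
    surv_raw = dict(raw.get("survival", {}))
    if "quartile_probs" in surv_raw:
        surv_raw["quartile_probs"] = tuple(surv_raw["quartile_probs"])
    return PipelineConfig(
        simulation=sim,
        qc=QcParameters(**raw.get("qc", {})),
        scan=ScanConfig(**raw.get("scan", {})),
        pgs=PgsConfig(**raw.get("pgs", {})),
        survival=SurvivalConfig(**surv_raw),
        stages=list(raw.get("stages", STAGE_ORDER)),
        seed=int(raw.get("seed", 0)),
    )


def dump_config(config: PipelineConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
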