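"""Simulation and analysis configuration.

:class:`SimulationConfig` collects every knob of the synthetic cohort
generator: acquisition geometry (grid, voxel size, TR, number of volumes),
the spectral model of the global grey-matter signal, the CSF inflow
coupling gains per clinical condition, per-network signal gains, noise
scales, group sizes, and the behavioural calibration (pre-to-post effect
sizes and target coupling-behaviour correlations).

Acquisition defaults mirror a standard 3T echo-planar resting-state
protocol: TR = 2 s and 185 volumes.  The test-scale grid is 24 x 24 x 12
voxels; the acquisition-faithful 64 x 64 x 36 grid is available through
``grid_dims``.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = ["SimulationConfig", "AnalysisConfig", "load_config"]

#: Clinical conditions a session can belong to.
CONDITIONS = ("HC", "PSA_pre", "PSA_post")

#: Resting-state networks with dedicated parcels in the phantom.
NETWORKS = ("LN", "SN", "DAN", "DMN")

# Per-subtest behavioural calibration: raw-score maximum, baseline mean and
# SD of the treated group, and the SD of the pre-to-post change.  Baselines
# follow the published treated-cohort summary; change SDs are chosen so that
# the default effect sizes produce scores comfortably inside the score range.
WAB_SUBTESTS: dict[str, dict[str, float]] = {
    "speech_fluency":           {"max": 10.0,  "pre_mean": 3.14,  "pre_sd": 1.75,  "delta_sd": 2.6},
    "information_content":      {"max": 10.0,  "pre_mean": 4.00,  "pre_sd": 1.52,  "delta_sd": 2.0},
    "yes_no_questions":         {"max": 60.0,  "pre_mean": 45.29, "pre_sd": 6.83,  "delta_sd": 7.3},
    "auditory_word_recognition": {"max": 60.0, "pre_mean": 44.45, "pre_sd": 8.49,  "delta_sd": 7.3},
    "sequential_order":         {"max": 80.0,  "pre_mean": 25.57, "pre_sd": 20.47, "delta_sd": 17.0},
    "repetition":               {"max": 100.0, "pre_mean": 71.72, "pre_sd": 15.32, "delta_sd": 13.2},
    "object_naming":            {"max": 60.0,  "pre_mean": 17.64, "pre_sd": 12.00, "delta_sd": 10.0},
    "word_fluency":             {"max": 20.0,  "pre_mean": 5.71,  "pre_sd": 2.61,  "delta_sd": 3.2},
    "sentence_completion":      {"max": 10.0,  "pre_mean": 2.79,  "pre_sd": 2.36,  "delta_sd": 2.4},
    "responsive_naming":        {"max": 10.0,  "pre_mean": 1.29,  "pre_sd": 1.64,  "delta_sd": 2.5},
}

# Default standardized pre-to-post treatment effects (Cohen's d) per subtest,
# consistent with the medium-to-large range reported for intensive
# speech-language therapy (roughly d = 0.45 to 1.4).
DEFAULT_BEHAVIOR_EFFECTS: dict[str, float] = {
    "speech_fluency": 0.92,
    "information_content": 1.27,
    "yes_no_questions": 0.45,
    "auditory_word_recognition": 1.24,
    "sequential_order": 1.37,
    "repetition": 1.23,
    "object_naming": 1.35,
    "word_fluency": 0.84,
    "sentence_completion": 1.14,
    "responsive_naming": 1.19,
}

# Which network's coupling change drives which language measure, and the
# target correlation between the coupling change and the score change.
# Negative: larger behavioural gains go with more negative coupling changes.
DEFAULT_ASSOC_R: dict[str, float] = {"LN": -0.543, "SN": -0.582, "DAN": -0.682, "DMN": 0.0}
DEFAULT_ASSOC_MEASURE: dict[str, str | None] = {
    "LN": "object_naming",
    "SN": "responsive_naming",
    "DAN": "sequential_order",
    "DMN": None,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic resting-state cohort.

    The seed fully determines every generated artefact; per-subject random
    substreams are derived from it with explicit spawn keys so that adding
    subjects never perturbs existing ones.
    """

    # --- acquisition geometry ---
    grid_dims: tuple[int, int, int] = (24, 24, 12)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 4.0)
    tr_s: float = 2.0
    n_timepoints: int = 185

    # --- global-signal spectral model ---
    f0_hz: float = 0.0625          # dominant frequency; quarter period = 4 s
    band_hz: tuple[float, float] = (0.01, 0.1)
    spectral_width_hz: float = 0.02  # Gaussian width around f0; 0 = pure tone

    # --- CSF inflow model ---
    # kappa scales how strongly the bottom-slice CSF signal follows the
    # negative temporal derivative of the global signal, per condition.
    kappa: dict[str, float] = field(
        default_factory=lambda: {"HC": 1.0, "PSA_pre": 0.45, "PSA_post": 0.85}
    )
    csf_baseline: float = 100.0
    csf_mod_amp: float = 0.05      # fractional modulation depth of the CSF signal
    noise_sd_csf: float = 2.5      # noise scale relative to the kappa term

    # --- BOLD voxel model ---
    network_gains: dict[str, float] = field(
        default_factory=lambda: {"LN": 1.0, "SN": 0.9, "DAN": 0.8, "DMN": 0.7}
    )
    gm_other_gain: float = 0.85
    wm_gain: float = 0.3
    lesion_gain: float = 0.4       # multiplicative signal attenuation inside the lesion
    lesion_noise_factor: float = 2.0
    bold_baseline: float = 100.0
    bold_mod_amp: float = 0.05
    noise_sd_bold: float = 1.0     # voxel noise relative to the signal term
    motion_amp_mm: float = 0.2

    # --- lesion geometry ---
    lesion_radius_mm: tuple[float, float] = (4.0, 10.0)  # uniform range across subjects

    # --- cohort composition ---
    n_hc: int = 35
    n_psa: int = 20
    n_treated: int = 14            # PSA subjects with a post-treatment session

    # --- tabular coupling model (condition-level distribution of the
    # whole-brain coupling value; used by the cohort-table generator) ---
    coupling_mean: dict[str, float] = field(
        default_factory=lambda: {"HC": -0.263, "PSA_pre": -0.191, "PSA_post": -0.245}
    )
    coupling_subject_sd: float = 0.06   # between-subject random intercept SD
    coupling_resid_sd: float = 0.057    # within-subject residual SD
    age_coupling_r: float = 0.374       # target correlation of coupling with age
    network_coupling_mean: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "LN":  {"HC": -0.26, "PSA_pre": -0.15, "PSA_post": -0.24},
            "SN":  {"HC": -0.28, "PSA_pre": -0.21, "PSA_post": -0.28},
            "DAN": {"HC": -0.26, "PSA_pre": -0.18, "PSA_post": -0.26},
            "DMN": {"HC": -0.24, "PSA_pre": -0.26, "PSA_post": -0.22},
        }
    )
    lesion_volume_logmean: float = 9.5  # log mm^3; exp(9.5) ~ 13 mL median
    lesion_volume_logsd: float = 0.8

    # --- behavioural model ---
    behavior_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BEHAVIOR_EFFECTS)
    )
    assoc_r: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ASSOC_R))
    assoc_measure: dict[str, str | None] = field(
        default_factory=lambda: dict(DEFAULT_ASSOC_MEASURE)
    )

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        lo, hi = self.band_hz
        if not (0 < lo < hi):
            raise ValueError(f"band_hz must satisfy 0 < low < high, got {self.band_hz}")
        if hi >= 0.5 / self.tr_s:
            raise ValueError("band_hz upper edge must be below the Nyquist frequency")
        if not (lo <= self.f0_hz <= hi):
            raise ValueError(f"f0_hz={self.f0_hz} must lie inside band_hz={self.band_hz}")
        if self.n_timepoints < 10:
            raise ValueError("n_timepoints must be >= 10")
        if len(self.grid_dims) != 3 or any(d < 4 for d in self.grid_dims):
            raise ValueError("grid_dims must be three axes of at least 4 voxels")
        if any(v <= 0 for v in self.voxel_size_mm) or self.tr_s <= 0:
            raise ValueError("voxel sizes and TR must be positive")
        for name, k in self.kappa.items():
            if k < 0:
                raise ValueError(f"kappa[{name}] must be >= 0")
        if any(g < 0 for g in self.network_gains.values()):
            raise ValueError("network gains must be >= 0")
        if min(self.noise_sd_bold, self.noise_sd_csf, self.motion_amp_mm) < 0:
            raise ValueError("noise and motion scales must be >= 0")
        if self.n_hc < 2 or self.n_psa < 2:
            raise ValueError("group sizes must be >= 2")
        if not (0 < self.n_treated <= self.n_psa):
            raise ValueError("n_treated must be in (0, n_psa]")
        for net, r in self.assoc_r.items():
            if abs(r) >= 1:
                raise ValueError(f"assoc_r[{net}]={r} is infeasible (|r| must be < 1)")
        if self.spectral_width_hz < 0:
            raise ValueError("spectral_width_hz must be >= 0")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["grid_dims"] = list(self.grid_dims)
        d["voxel_size_mm"] = list(self.voxel_size_mm)
        d["band_hz"] = list(self.band_hz)
        d["lesion_radius_mm"] = list(self.lesion_radius_mm)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("grid_dims", "voxel_size_mm", "band_hz", "lesion_radius_mm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        """Stable hash of the canonicalized configuration."""
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class AnalysisConfig:
    """Options of the analysis half of the pipeline."""

    max_lag_s: float = 20.0        # symmetric lag grid for cross-correlation
    coupling_lag_s: float = 4.0    # lag at which coupling strength is read off
    band_hz: tuple[float, float] = (0.01, 0.1)
    filter_order: int = 4          # Butterworth order per pass (applied forward-backward)
    alpha: float = 0.05
    fdr_q: float = 0.05
    power_target: float = 0.80
    power_tails: int = 2

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["band_hz"] = list(self.band_hz)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AnalysisConfig":
        d = dict(d)
        if "band_hz" in d:
            d["band_hz"] = tuple(d["band_hz"])
        return cls(**d)


def load_config(path: str) -> tuple[SimulationConfig, AnalysisConfig]:
    """Read a YAML config with optional ``simulation:`` and ``analysis:`` blocks."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = SimulationConfig.from_dict(raw.get("simulation", {}))
    ana = AnalysisConfig.from_dict(raw.get("analysis", {}))
    return sim, ana
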