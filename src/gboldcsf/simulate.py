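"""Synthetic resting-state cohort generator.

Builds seeded phantom subjects carrying the statistical structure the
coupling analysis assumes, so every downstream stage can be exercised
without any real MRI data:

* a band-limited (0.01-0.1 Hz) global grey-matter signal u(t) with a
  dominant frequency f0 (default 0.0625 Hz, so a quarter period is 4 s);
* a bottom-slice CSF inflow signal proportional to the *negative temporal
  derivative* of u(t) -- the inflow mechanism that produces a negative
  cross-correlation peak at a +4 s lag and a derivative cross-correlation
  peak at lag 0;
* four network parcels (LN, SN, DAN, DMN) with distinct signal gains, a
  white-matter compartment with its own nuisance fluctuation, left
  hemisphere lesions for patients, and motion-correlated artefacts;
* a behavioural table (WAB subtest scores pre/post therapy) calibrated to
  configured effect sizes and coupling-behaviour correlations.

All randomness flows through one seed; per-subject substreams are derived
with explicit spawn keys (see :func:`gboldcsf._utils.rng_for`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.ndimage import gaussian_filter1d

from .config import NETWORKS, WAB_SUBTESTS, SimulationConfig
from .core import LABEL_CLASSES, MotionParams, PhantomLabels, Volume4D
from ._utils import rng_for, zscore

__all__ = [
    "generate_global_signal",
    "generate_csf_signal",
    "generate_motion",
    "generate_lesion_mask",
    "make_phantom_labels",
    "generate_subject",
    "generate_imaging_cohort",
    "simulate_coupling_table",
    "generate_wab_cohort",
]

# Demographics of the two groups: age mean/SD, fraction male.
AGE_DIST = {"HC": (48.0, 9.14), "PSA": (46.5, 9.45)}
FRAC_MALE = 0.55

# Stream ids used to key per-subject random substreams.
_STREAM_LABELS = 0
_STREAM_SESSION = {"HC": 1, "PSA_pre": 1, "PSA_post": 2}
_STREAM_BEHAVIOR = 3
_STREAM_TABLE = 4
_STREAM_DEMOGRAPHICS = 5


# ---------------------------------------------------------------------------
# signals
# ---------------------------------------------------------------------------

def generate_global_signal(
    config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Band-limited global grey-matter signal, zero mean and unit variance.

    The signal is synthesized in the frequency domain: Fourier amplitudes
    follow a Gaussian bump of width ``spectral_width_hz`` centred on
    ``f0_hz``, restricted to the passband, with uniform random phases.
    With ``spectral_width_hz == 0`` the signal degenerates to a pure
    sinusoid at ``f0_hz`` with a random phase.
    """
    n, tr = config.n_timepoints, config.tr_s
    lo, hi = config.band_hz
    freqs = np.fft.rfftfreq(n, tr)
    inband = (freqs >= lo) & (freqs <= hi)
    if inband.sum() < 3:
        raise ValueError(
            f"run too short to resolve the passband: only {int(inband.sum())} "
            f"frequency bins fall inside {config.band_hz} at n={n}, TR={tr}s"
        )
    if config.spectral_width_hz == 0:
        t = np.arange(n) * tr
        phase = rng.uniform(0.0, 2.0 * np.pi)
        return zscore(np.sin(2.0 * np.pi * config.f0_hz * t + phase))
    amp = np.exp(-0.5 * ((freqs - config.f0_hz) / config.spectral_width_hz) ** 2)
    amp[~inband] = 0.0
    phases = rng.uniform(0.0, 2.0 * np.pi, size=freqs.size)
    coeffs = amp * np.exp(1j * phases)
    coeffs[0] = 0.0
    u = np.fft.irfft(coeffs, n)
    return zscore(u)


def generate_csf_signal(
    u: np.ndarray,
    kappa: float,
    noise_sd: float,
    rng: np.random.Generator,
    *,
    tr_s: float = 2.0,
    baseline: float = 100.0,
    mod_amp: float = 0.05,
) -> np.ndarray:
    """CSF inflow signal driven by the negative derivative of the global signal.

    c(t) = baseline * (1 + mod_amp * (kappa * z(-du/dt) + noise_sd * eps(t)))

    where z() standardizes. With ``noise_sd = 0`` the correlation between
    c(t) and -du/dt at lag 0 is exactly 1; with ``kappa = 0`` and no noise
    the signal is the constant baseline. The inflow polarity convention is
    owned by this model, so negative kappa is rejected.
    """
    u = np.asarray(u, dtype=float)
    if u.size < 3:
        raise ValueError("global signal must have at least 3 samples")
    if kappa < 0:
        raise ValueError("kappa must be >= 0 (polarity is fixed by the inflow model)")
    if baseline <= 0:
        raise ValueError("baseline must be strictly positive")
    d = -np.gradient(u, tr_s)
    drive = kappa * zscore(d)
    noise = noise_sd * rng.standard_normal(u.size) if noise_sd > 0 else 0.0
    return baseline * (1.0 + mod_amp * (drive + noise))


def generate_motion(
    config: SimulationConfig, rng: np.random.Generator
) -> MotionParams:
    """Smooth random-walk realignment traces scaled to ``motion_amp_mm``."""
    n = config.n_timepoints
    if config.motion_amp_mm == 0:
        return MotionParams(np.zeros((n, 6)))
    walk = np.cumsum(rng.standard_normal((n, 6)), axis=0)
    walk = gaussian_filter1d(walk, sigma=2.0, axis=0)
    walk -= walk.mean(axis=0)
    rms = walk.std(axis=0)
    rms[rms == 0] = 1.0
    walk /= rms
    scale = np.array([config.motion_amp_mm] * 3 + [config.motion_amp_mm / 50.0] * 3)
    return MotionParams(walk * scale)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def generate_lesion_mask(
    config: SimulationConfig,
    rng: np.random.Generator,
    radius_mm: float | None = None,
) -> np.ndarray:
    """Connected spherical lesion blob restricted to the left grid half.

    "Left" is the lower-x half of the grid. The radius is drawn uniformly
    from ``config.lesion_radius_mm`` unless given; radius 0 yields an
    empty mask.
    """
    nx, ny, nz = config.grid_dims
    vx, vy, vz = config.voxel_size_mm
    if radius_mm is None:
        radius_mm = float(rng.uniform(*config.lesion_radius_mm))
    cx = rng.uniform(0.18 * nx, 0.38 * nx)
    cy = rng.uniform(0.35 * ny, 0.65 * ny)
    cz = rng.uniform(0.45 * nz, 0.75 * nz)
    if radius_mm <= 0:
        return np.zeros(config.grid_dims, dtype=bool)
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    dist2 = (
        ((ii - cx) * vx) ** 2 + ((jj - cy) * vy) ** 2 + ((kk - cz) * vz) ** 2
    )
    mask = dist2 <= radius_mm**2
    mask[nx // 2 :, :, :] = False  # strictly left hemisphere
    return mask


def make_phantom_labels(
    config: SimulationConfig,
    rng: np.random.Generator,
    with_lesion: bool = False,
) -> PhantomLabels:
    """Tissue/network label volume of the phantom head.

    An ellipsoidal brain holds an inner WM core and a GM shell. The upper
    GM shell is split into four quadrant parcels standing in for the LN,
    SN, DAN and DMN; the lower shell is unassigned grey matter. A compact
    CSF blob (about 20 voxels at the default grid) sits on the lowest
    slice, where inflow effects are read out. Patient phantoms get a
    left-hemisphere lesion carved out of GM/WM.
    """
    nx, ny, nz = config.grid_dims
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    x = (ii - cx) / (0.48 * nx)
    y = (jj - cy) / (0.48 * ny)
    z = (kk - cz) / (0.52 * nz)
    r2 = x**2 + y**2 + z**2
    brain = r2 <= 1.0
    wm = r2 <= 0.22
    gm = brain & ~wm

    lab = np.zeros(config.grid_dims, dtype=np.int16)
    lab[gm] = LABEL_CLASSES["GM_other"]
    lab[wm] = LABEL_CLASSES["WM"]

    upper = kk > cz
    quads = {
        "GM_LN": (ii <= cx) & (jj <= cy),
        "GM_SN": (ii > cx) & (jj <= cy),
        "GM_DAN": (ii <= cx) & (jj > cy),
        "GM_DMN": (ii > cx) & (jj > cy),
    }
    for name, quad in quads.items():
        lab[gm & upper & quad] = LABEL_CLASSES[name]

    # bottom-slice CSF blob (inflow readout region)
    disc = ((ii - cx) ** 2 + (jj - cy) ** 2 <= 2.5**2) & (kk == 0)
    lab[disc] = LABEL_CLASSES["CSF_bottom"]

    if with_lesion:
        lesion = generate_lesion_mask(config, rng)
        lab[lesion & ((gm | wm) & ~disc)] = LABEL_CLASSES["lesion"]

    return PhantomLabels(lab, dict(LABEL_CLASSES), config.voxel_size_mm)


# ---------------------------------------------------------------------------
# subjects
# ---------------------------------------------------------------------------

def generate_subject(
    config: SimulationConfig,
    condition: str,
    rng: np.random.Generator,
    labels: PhantomLabels | None = None,
) -> tuple[Volume4D, PhantomLabels, MotionParams]:
    """One synthetic 4D session for a given clinical condition.

    GM voxel time series are the global signal scaled by the network gain
    plus voxel noise; WM carries an attenuated global component plus its
    own shared nuisance fluctuation; bottom-slice CSF voxels carry the
    derivative-driven inflow signal; lesion voxels get an attenuated,
    noisier signal. A shared motion-locked artefact with amplitude
    ``motion_amp_mm`` is added throughout the brain.
    """
    if condition not in config.kappa:
        raise ValueError(
            f"condition {condition!r} has no kappa entry; known: {sorted(config.kappa)}"
        )
    if labels is None:
        labels = make_phantom_labels(config, rng, with_lesion=condition != "HC")

    n = config.n_timepoints
    u = generate_global_signal(config, rng)
    motion = generate_motion(config, rng)
    wm_fluct = zscore(gaussian_filter1d(rng.standard_normal(n), sigma=4.0))
    csf_shared = generate_csf_signal(
        u,
        config.kappa[condition],
        config.noise_sd_csf,
        rng,
        tr_s=config.tr_s,
        baseline=config.csf_baseline,
        mod_amp=config.csf_mod_amp,
    )
    if config.motion_amp_mm > 0:
        motion_art = zscore(motion.params[:, :3].sum(axis=1))
    else:
        motion_art = np.zeros(n)

    base, amp, sd = config.bold_baseline, config.bold_mod_amp, config.noise_sd_bold
    cmap = labels.class_map
    lab = labels.label_volume
    data = np.zeros(config.grid_dims + (n,), dtype=np.float64)

    def fill(mask: np.ndarray, signal: np.ndarray, noise_sd: float) -> None:
        nvox = int(mask.sum())
        if nvox == 0:
            return
        eps = rng.standard_normal((nvox, n)) if noise_sd > 0 else 0.0
        series = base * (
            1.0 + amp * (signal[None, :] + config.motion_amp_mm * motion_art[None, :]
                         + noise_sd * eps)
        )
        data[mask] = series

    gain_of = {
        "GM_LN": config.network_gains["LN"],
        "GM_SN": config.network_gains["SN"],
        "GM_DAN": config.network_gains["DAN"],
        "GM_DMN": config.network_gains["DMN"],
        "GM_other": config.gm_other_gain,
    }
    for name in ("GM_LN", "GM_SN", "GM_DAN", "GM_DMN", "GM_other"):
        fill(lab == cmap[name], gain_of[name] * u, sd)
    fill(lab == cmap["WM"], config.wm_gain * u + 0.8 * wm_fluct, sd)
    fill(
        lab == cmap["lesion"],
        config.lesion_gain * config.gm_other_gain * u,
        sd * config.lesion_noise_factor,
    )

    # CSF: shared inflow signal plus small independent voxel noise
    csf_mask = lab == cmap["CSF_bottom"]
    ncsf = int(csf_mask.sum())
    if ncsf:
        eps = rng.standard_normal((ncsf, n)) if sd > 0 else 0.0
        data[csf_mask] = csf_shared[None, :] + config.csf_baseline * (
            config.csf_mod_amp * 0.2 * eps
        )

    vol = Volume4D(data, config.voxel_size_mm, config.tr_s)
    return vol, labels, motion


def generate_imaging_cohort(config: SimulationConfig):
    """Yield per-session phantom records for the whole cohort.

    Yields dicts with keys: subject_id, group, condition, session, age,
    sex (1 = male), volume, labels, motion. Treated patients (the first
    ``n_treated`` PSA subjects) contribute both a pre- and a
    post-treatment session sharing one label volume.
    """
    seed = config.seed
    idx = 0
    for group, n_sub in (("HC", config.n_hc), ("PSA", config.n_psa)):
        for i in range(n_sub):
            demo_rng = rng_for(seed, idx, _STREAM_DEMOGRAPHICS)
            mu, sdev = AGE_DIST[group]
            age = float(np.clip(demo_rng.normal(mu, sdev), 25.0, 80.0))
            sex = int(demo_rng.random() < FRAC_MALE)
            label_rng = rng_for(seed, idx, _STREAM_LABELS)
            labels = make_phantom_labels(config, label_rng, with_lesion=group == "PSA")
            conditions = ["HC"] if group == "HC" else ["PSA_pre"]
            if group == "PSA" and i < config.n_treated:
                conditions.append("PSA_post")
            for cond in conditions:
                sess_rng = rng_for(seed, idx, _STREAM_SESSION[cond])
                vol, _, motion = generate_subject(config, cond, sess_rng, labels=labels)
                yield {
                    "subject_id": f"sub-{idx + 1:03d}",
                    "group": group,
                    "condition": cond,
                    "session": "post" if cond == "PSA_post" else "pre",
                    "age": age,
                    "sex": sex,
                    "volume": vol,
                    "labels": labels,
                    "motion": motion,
                }
            idx += 1


# ---------------------------------------------------------------------------
# tabular cohort (condition-level coupling distribution, no imaging)
# ---------------------------------------------------------------------------

def simulate_coupling_table(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Cohort table of coupling values drawn from the condition-level model.

    Whole-brain coupling for subject i in condition c is

        y_ic = mean[c] + slope * (age_i - 47.5) + b_i + eps_ic

    with a subject random intercept b_i and residual noise, the age slope
    calibrated to ``age_coupling_r``. Network couplings follow
    ``network_coupling_mean`` with a shared fraction of b_i. This is the
    generator behind the statistical battery's calibration tests; it
    bypasses image synthesis entirely.
    """
    if rng is None:
        rng = rng_for(config.seed, _STREAM_TABLE)
    sd_tot = np.hypot(config.coupling_subject_sd, config.coupling_resid_sd)
    r = config.age_coupling_r
    age_sd = AGE_DIST["HC"][1]
    slope = 0.0 if sd_tot == 0 else (r / np.sqrt(max(1e-12, 1 - r**2))) * sd_tot / age_sd

    rows = []
    idx = 0
    for group, n_sub in (("HC", config.n_hc), ("PSA", config.n_psa)):
        mu, sdev = AGE_DIST[group]
        for i in range(n_sub):
            age = float(np.clip(rng.normal(mu, sdev), 25.0, 80.0))
            sex = int(rng.random() < FRAC_MALE)
            b_i = rng.normal(0.0, config.coupling_subject_sd)
            lesion = (
                float(np.exp(rng.normal(config.lesion_volume_logmean,
                                        config.lesion_volume_logsd)))
                if group == "PSA"
                else 0.0
            )
            conditions = ["HC"] if group == "HC" else ["PSA_pre"]
            if group == "PSA" and i < config.n_treated:
                conditions.append("PSA_post")
            for cond in conditions:
                row = {
                    "subject_id": f"sub-{idx + 1:03d}",
                    "group": group,
                    "condition": cond,
                    "age": age,
                    "sex": sex,
                    "lesion_volume_mm3": lesion,
                }
                row["coupling"] = (
                    config.coupling_mean[cond]
                    + slope * (age - 47.5)
                    + b_i
                    + rng.normal(0.0, config.coupling_resid_sd)
                )
                for net in NETWORKS:
                    row[f"coupling_{net}"] = (
                        config.network_coupling_mean[net][cond]
                        + 0.7 * b_i
                        + rng.normal(0.0, config.coupling_resid_sd)
                    )
                rows.append(row)
            idx += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# behaviour
# ---------------------------------------------------------------------------

def generate_wab_cohort(
    config: SimulationConfig,
    delta_coupling: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Pre/post WAB raw subtest scores for the treated subjects.

    ``delta_coupling`` needs a ``subject_id`` column plus one
    ``delta_<network>`` column per network whose coupling change should
    drive a language measure (per ``config.assoc_measure``). For each
    subtest the standardized change is

        delta / delta_sd = d + r * z + sqrt(1 - r^2) * eps

    where d is the configured effect size, z the standardized coupling
    change of the linked network and r the target association (negative r:
    larger gains go with more negative coupling changes). Scores are
    truncated to [0, max] of each subtest.
    """
    if rng is None:
        rng = rng_for(config.seed, _STREAM_BEHAVIOR)
    if delta_coupling["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id in delta_coupling table")
    n = len(delta_coupling)
    measure_to_net = {
        m: net for net, m in config.assoc_measure.items() if m is not None
    }

    out = pd.DataFrame({"subject_id": delta_coupling["subject_id"].to_numpy()})
    for subtest, info in WAB_SUBTESTS.items():
        d = config.behavior_effects.get(subtest, 0.0)
        net = measure_to_net.get(subtest)
        r = config.assoc_r.get(net, 0.0) if net else 0.0
        col = f"delta_{net}" if net else None
        if col is not None and col in delta_coupling.columns:
            z = zscore(delta_coupling[col].to_numpy(dtype=float))
        else:
            r, z = 0.0, np.zeros(n)

        mu, sdev, mx = info["pre_mean"], info["pre_sd"], info["max"]
        a, b = (0.0 - mu) / sdev, (mx - mu) / sdev
        pre = sps.truncnorm.rvs(a, b, loc=mu, scale=sdev, size=n, random_state=rng)
        eps = rng.standard_normal(n)
        delta = info["delta_sd"] * (d + r * z + np.sqrt(1.0 - r**2) * eps)
        post = np.clip(pre + delta, 0.0, mx)
        out[f"{subtest}_pre"] = pre
        out[f"{subtest}_post"] = post
    return out
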