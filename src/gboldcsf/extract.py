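"""Scalar time-series extraction from preprocessed volumes.

Produces the three signal families the coupling analysis runs on: the
global grey-matter BOLD signal (voxel-wise z-score, then average, then a
final re-z-score for comparability), per-network signals by the same
recipe restricted to a network parcel, and the bottom-slice CSF signal
expressed as a fraction of its temporal mean (so the inflow polarity is
preserved). Lesion volume is read off a binary mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import NETWORKS
from .core import PhantomLabels, Volume4D
from ._utils import zscore

__all__ = [
    "extract_gbold",
    "extract_csf",
    "extract_network_signal",
    "lesion_volume",
    "SubjectTimecourses",
    "extract_timecourses",
]

logger = logging.getLogger(__name__)


def _z_average_z(vol: Volume4D, mask: np.ndarray, what: str) -> np.ndarray:
    """z-score each masked voxel over time, average across voxels, re-z-score."""
    if mask.shape != vol.shape[:3]:
        raise ValueError(f"{what} mask shape {mask.shape} does not match volume")
    if not mask.any():
        raise ValueError(f"empty {what} mask")
    series = vol.data[mask]
    sd = series.std(axis=1)
    n_dead = int((sd == 0).sum())
    if n_dead == series.shape[0]:
        raise ValueError(f"all {what} voxels have zero temporal variance")
    if n_dead:
        logger.info("excluding %d zero-variance voxel(s) from %s mask", n_dead, what)
        series = series[sd > 0]
    mean_sig = zscore(series, axis=1).mean(axis=0)
    if mean_sig.std() == 0:
        logger.warning("degenerate %s signal: voxel z-scores cancel to a flat mean", what)
        return mean_sig
    return zscore(mean_sig)


def extract_gbold(vol: Volume4D, gm_mask: np.ndarray) -> np.ndarray:
    """Global grey-matter BOLD signal in z-units (mean 0, SD 1)."""
    return _z_average_z(vol, gm_mask, "grey-matter")


def extract_network_signal(
    vol: Volume4D, labels: PhantomLabels, network: str
) -> np.ndarray:
    """Network-restricted BOLD signal; same recipe as :func:`extract_gbold`."""
    if network not in NETWORKS:
        raise ValueError(f"unknown network {network!r}; expected one of {NETWORKS}")
    mask = labels.mask(f"GM_{network}")
    if not mask.any():
        raise ValueError(f"network {network} has no voxels in the label volume")
    return _z_average_z(vol, mask, f"network {network}")


def extract_csf(vol: Volume4D, csf_mask: np.ndarray) -> np.ndarray:
    """Bottom-slice CSF signal as a fraction of its temporal mean (mean exactly 1).

    The mask must be confined to the lowest slice (z = 0): that is where
    fresh inflowing fluid, not yet saturated by the excitation pulses,
    produces the inflow signal increase the analysis relies on.
    """
    if csf_mask.shape != vol.shape[:3]:
        raise ValueError("CSF mask shape does not match volume")
    if not csf_mask.any():
        raise ValueError("empty CSF mask")
    if csf_mask[:, :, 1:].any():
        raise ValueError("CSF mask must be restricted to the lowest slice (z=0)")
    series = vol.data[csf_mask].mean(axis=0)
    m = series.mean()
    if m <= 0:
        raise ValueError(f"CSF signal temporal mean must be positive, got {m:.4g}")
    return series / m


def lesion_volume(mask: np.ndarray, voxel_size_mm: tuple[float, float, float]) -> float:
    """Lesion volume in mm^3: voxel count times voxel volume."""
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.isin(vals, [0, 1]).all():
        raise ValueError("lesion mask must be binary")
    voxel_mm3 = float(np.prod(voxel_size_mm))
    return float(mask.sum()) * voxel_mm3


@dataclass
class SubjectTimecourses:
    """All extracted signals of one session, on a common TR and length."""

    subject_id: str
    session: str
    tr_s: float
    gbold: np.ndarray
    csf: np.ndarray
    networks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.gbold.size
        if self.csf.size != n or any(v.size != n for v in self.networks.values()):
            raise ValueError("all timecourses of a session must share one length")


def extract_timecourses(
    gbold_vol: Volume4D,
    csf_vol: Volume4D,
    labels: PhantomLabels,
    subject_id: str = "sub-001",
    session: str = "pre",
) -> SubjectTimecourses:
    """Extract gBOLD, CSF and the four network signals for one session.

    ``gbold_vol`` and ``csf_vol`` are the outputs of the two preprocessing
    paths applied to the same raw session.
    """
    gm = labels.gm_mask()
    csf_mask = labels.mask("CSF_bottom")
    nets = {}
    for net in NETWORKS:
        try:
            nets[net] = extract_network_signal(gbold_vol, labels, net)
        except ValueError as exc:
            logger.warning("skipping network %s: %s", net, exc)
    return SubjectTimecourses(
        subject_id=subject_id,
        session=session,
        tr_s=gbold_vol.tr_s,
        gbold=extract_gbold(gbold_vol, gm),
        csf=extract_csf(csf_vol, csf_mask),
        networks=nets,
    )
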