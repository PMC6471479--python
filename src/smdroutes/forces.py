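"""Ensemble-average force profiles and rupture-force extraction.

The instantaneous spring force of every sample of every replica is binned by
restraint displacement (not time), so replicas of different lengths align.
The rupture force is the global maximum of the (optionally smoothed) mean
force profile. Forces are surfaced both in kcal·mol⁻¹·Å⁻¹ and in pN per
molecule through the standard conversion (1 kcal·mol⁻¹·Å⁻¹ ≈ 69.477 pN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .pmf import WorkEnsemble
from .units import KCAL_PER_MOL_ANGSTROM_IN_PN


@dataclass
class ForceProfile:
    """Mean pulling force vs restraint displacement for one route."""

    route_id: str
    bin_centers: np.ndarray       # Å
    mean_force: np.ndarray        # kcal·mol⁻¹·Å⁻¹; NaN in empty bins
    n_contributing: np.ndarray    # replicas with samples in each bin

    def __post_init__(self) -> None:
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bins must be strictly increasing")

    @property
    def mean_force_pN(self) -> np.ndarray:
        return self.mean_force * KCAL_PER_MOL_ANGSTROM_IN_PN

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.mean_force)


def kcalmolA_to_pN(f: float) -> float:
    """Convert a per-mole force to a per-molecule force in piconewtons."""
    return f * KCAL_PER_MOL_ANGSTROM_IN_PN


def average_force_profile(ensemble: WorkEnsemble,
                          bin_width: float = 0.25) -> ForceProfile:
    """Mean instantaneous spring force per half-open displacement bin.

    All samples of all replicas are pooled; a bin with no samples is flagged
    undefined (NaN).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    max_disp = max(tr.final_displacement for tr in ensemble.trajectories)
    n_bins = max(1, int(math.floor(max_disp / bin_width)) + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    touched = np.zeros((len(ensemble.trajectories), n_bins), dtype=bool)

    for r, tr in enumerate(ensemble.trajectories):
        idx = np.floor_divide(tr.displacement, bin_width).astype(int)
        idx = np.clip(idx, 0, n_bins - 1)
        np.add.at(sums, idx, tr.force)
        np.add.at(counts, idx, 1)
        touched[r, np.unique(idx)] = True

    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (np.arange(n_bins) + 0.5) * bin_width
    return ForceProfile(route_id=ensemble.route_id, bin_centers=centers,
                        mean_force=mean, n_contributing=touched.sum(axis=0))


def smooth_profile(profile: ForceProfile, window: int = 5) -> ForceProfile:
    """Centered moving average; endpoint windows shrink symmetrically.

    ``window`` must be odd; window = 1 is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    n = len(profile.mean_force)
    if window > n:
        raise ValueError(f"window {window} exceeds profile length {n}")
    if window == 1:
        return replace(profile, mean_force=profile.mean_force.copy())
    half = window // 2
    out = np.empty(n)
    x = profile.mean_force
    for i in range(n):
        seg = x[max(0, i - half):i + half + 1]   # truncated near the ends
        out[i] = np.nanmean(seg) if not np.all(np.isnan(seg)) else np.nan
    return replace(profile, mean_force=out)


def rupture_force(profile: ForceProfile) -> tuple[float, float]:
    """Global maximum of the mean-force profile and its displacement.

    Ties break toward the smaller displacement. Apply smoothing first if a
    de-noised rupture point is wanted.
    """
    defined = profile.defined
    if not defined.any():
        raise ValueError("profile has no defined bins")
    vals = profile.mean_force[defined]
    cents = profile.bin_centers[defined]
    i = int(np.argmax(vals))
    return float(vals[i]), float(cents[i])
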