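"""PMF estimation from nonequilibrium pulling work.

Two one-sided estimators of the free-energy difference along the pulling
coordinate are provided:

* the exponential (Jarzynski) average,  ΔF = −kBT·ln⟨e^(−βW)⟩, exact for any
  pulling speed but noisy when work fluctuations exceed a few kBT;
* the second-order cumulant expansion,  ΔF ≈ ⟨W⟩ − δW²/(2kBT) with
  δW² = ⟨W²⟩ − ⟨W⟩² (population variance), exact when the work distribution
  is Gaussian and far better behaved at small sample sizes.

The reaction coordinate is the restraint-center displacement λ(t) − λ(0)
(stiff-spring convention): work is a function of the protocol, not of the
fluctuating system coordinate. Profiles are binned in that displacement,
anchored to zero at the first bin, and carry bootstrap standard errors from
resampling replicas.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .synthetic import PullingProtocol, WorkTrajectory
from .units import kBT as thermal_energy

logger = logging.getLogger(__name__)

ESTIMATORS = ("exponential", "cumulant2")

#: robust-SD factor: MAD × 1.4826 estimates σ for Gaussian data
MAD_TO_SD = 1.4826


class FilterError(RuntimeError):
    """Raised when a replica filter would discard every replica."""


@dataclass
class WorkEnsemble:
    """Replicas of one pulling route plus the shared protocol."""

    route_id: str
    trajectories: list[WorkTrajectory]
    protocol: PullingProtocol
    beta: float | None = None   # (kcal/mol)⁻¹; None → 1/kBT(protocol.temperature)

    def __post_init__(self) -> None:
        if not self.trajectories:
            raise ValueError("ensemble must contain at least one trajectory")
        if self.beta is None:
            self.beta = 1.0 / thermal_energy(self.protocol.temperature)
        if self.beta <= 0:
            raise ValueError("beta must be > 0")

    def __len__(self) -> int:
        return len(self.trajectories)

    @property
    def kBT(self) -> float:
        return 1.0 / self.beta

    @property
    def final_works(self) -> np.ndarray:
        return np.asarray([tr.final_work for tr in self.trajectories])


@dataclass
class PMFProfile:
    """Binned free-energy profile along the restraint displacement."""

    route_id: str
    bin_centers: np.ndarray      # Å from the start of pulling
    delta_F: np.ndarray          # kcal/mol; NaN where undefined
    stderr: np.ndarray           # bootstrap SE, kcal/mol
    n_contributing: np.ndarray   # replicas contributing per bin
    estimator: str

    def __post_init__(self) -> None:
        if self.estimator not in ESTIMATORS:
            raise ValueError(f"estimator must be one of {ESTIMATORS}")
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bins must be strictly increasing")
        defined = ~np.isnan(self.delta_F)
        if defined.any() and self.delta_F[np.argmax(defined)] != 0.0:
            raise ValueError("delta_F must be 0 at the first defined bin")
        if np.any(self.stderr[defined] < 0):
            raise ValueError("stderr must be >= 0")

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.delta_F)


@dataclass
class EnsembleWorkSummary:
    """Mean ± sample SD of final pulling works for one route."""

    route_id: str
    n_used: int
    n_discarded: int
    mean_final_work: float
    sd_final_work: float
    single_replica: bool = False


@dataclass
class FilterPolicy:
    """Replica-rejection policy: drop incomplete runs, then robust work
    outliers beyond median ± c·1.4826·MAD of the completed finals.

    MAD = 0 (no spread) keeps everything — a degenerate distribution has no
    outliers.
    """

    require_completed: bool = True
    mad_constant: float = 4.0


@dataclass
class DiscardedReplica:
    replica_id: int
    reason: str
    final_work: float


# ---------------------------------------------------------------------------
# Filtering and summaries
# ---------------------------------------------------------------------------

def filter_replicas(ensemble: WorkEnsemble,
                    policy: FilterPolicy | None = None
                    ) -> tuple[WorkEnsemble, list[DiscardedReplica]]:
    """Drop incomplete replicas and robust final-work outliers."""
    policy = policy or FilterPolicy()
    discarded: list[DiscardedReplica] = []

    survivors = []
    for tr in ensemble.trajectories:
        if policy.require_completed and not tr.completed:
            discarded.append(DiscardedReplica(tr.replica_id, "incomplete", tr.final_work))
        else:
            survivors.append(tr)

    if survivors:
        finals = np.asarray([tr.final_work for tr in survivors])
        med = float(np.median(finals))
        mad = float(np.median(np.abs(finals - med)))
        if mad > 0.0:
            cut = policy.mad_constant * MAD_TO_SD * mad
            kept = []
            for tr, w in zip(survivors, finals):
                if abs(w - med) > cut:
                    discarded.append(DiscardedReplica(
                        tr.replica_id,
                        f"final work {w:.4g} outside median {med:.4g} ± {cut:.4g}",
                        float(w)))
                else:
                    kept.append(tr)
            survivors = kept

    if not survivors:
        raise FilterError(
            f"filter policy (require_completed={policy.require_completed}, "
            f"c={policy.mad_constant} on the MAD scale) discarded all "
            f"{len(ensemble)} replicas of route {ensemble.route_id!r}")

    logger.info("route %s: kept %d / %d replicas (%d discarded)",
                ensemble.route_id, len(survivors), len(ensemble), len(discarded))
    filtered = WorkEnsemble(route_id=ensemble.route_id, trajectories=survivors,
                            protocol=ensemble.protocol, beta=ensemble.beta)
    return filtered, discarded


def summarize_work(ensemble: WorkEnsemble) -> EnsembleWorkSummary:
    """Mean and sample SD (n−1 denominator) of final works, with counts.

    Apply to an already-filtered ensemble; ``n_discarded`` here is 0 by
    construction and is normally overwritten by the caller that did the
    filtering.
    """
    finals = ensemble.final_works
    n = len(finals)
    sd = float(np.std(finals, ddof=1)) if n > 1 else 0.0
    return EnsembleWorkSummary(
        route_id=ensemble.route_id, n_used=n, n_discarded=0,
        mean_final_work=float(np.mean(finals)), sd_final_work=sd,
        single_replica=(n == 1))


# ---------------------------------------------------------------------------
# Jarzynski estimators
# ---------------------------------------------------------------------------

def work_at_displacement(traj: WorkTrajectory, s: float) -> float:
    """Accumulated work when the restraint has moved ``s`` Å, by linear
    interpolation in restraint displacement (not in the fluctuating ξ)."""
    disp = traj.displacement
    if s < 0 or s > disp[-1]:
        raise ValueError(
            f"displacement {s} outside trajectory range [0, {disp[-1]:.6g}]")
    return float(np.interp(s, disp, traj.work))


def jarzynski_exponential(works: Iterable[float], kbt: float) -> float:
    """ΔF = −kBT·ln⟨e^(−W/kBT)⟩ via a log-sum-exp shift by min(W)."""
    w = np.asarray(list(works) if not isinstance(works, np.ndarray) else works,
                   dtype=float)
    if w.size == 0:
        raise ValueError("need at least one work value")
    if kbt <= 0:
        raise ValueError("kBT must be > 0")
    w_min = float(np.min(w))
    log_mean = math.log(float(np.mean(np.exp(-(w - w_min) / kbt))))
    return w_min - kbt * log_mean


def jarzynski_cumulant2(works: Iterable[float], kbt: float) -> float:
    """ΔF ≈ ⟨W⟩ − (⟨W²⟩ − ⟨W⟩²)/(2kBT), population (÷n) variance."""
    w = np.asarray(list(works) if not isinstance(works, np.ndarray) else works,
                   dtype=float)
    if w.size < 2:
        raise ValueError(
            "cumulant estimator needs >= 2 work values (variance undefined); "
            "use the exponential estimator for a single replica")
    if kbt <= 0:
        raise ValueError("kBT must be > 0")
    var = float(np.var(w))            # population variance, matching δW² = ⟨W²⟩−⟨W⟩²
    return float(np.mean(w)) - var / (2.0 * kbt)


_ESTIMATOR_FN = {"exponential": jarzynski_exponential,
                 "cumulant2": jarzynski_cumulant2}


# ---------------------------------------------------------------------------
# Profiles, barriers, ranking
# ---------------------------------------------------------------------------

def build_pmf(ensemble: WorkEnsemble, bin_width: float = 0.25,
              estimator: str = "cumulant2", n_boot: int = 200,
              seed: int = 0) -> PMFProfile:
    """Estimate the PMF on half-open displacement bins [a, a+w).

    Per bin, the work of every replica whose trajectory covers the bin center
    is interpolated there and the chosen estimator applied across replicas;
    the profile is anchored so the first bin is exactly 0. Bins reached by
    too few replicas (< 1 exponential, < 2 cumulant) are flagged undefined
    (NaN). Standard errors come from ``n_boot`` bootstrap resamples of
    replicas, each resample re-anchored at the first bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if estimator not in ESTIMATORS:
        raise ValueError(f"estimator must be one of {ESTIMATORS}")
    kbt = ensemble.kBT
    min_n = 1 if estimator == "exponential" else 2

    reach = np.asarray([tr.final_displacement for tr in ensemble.trajectories])
    max_disp = float(reach.max())
    n_bins = int(math.floor(max_disp / bin_width)) + 1
    centers = (np.arange(n_bins) + 0.5) * bin_width
    centers = centers[centers <= max_disp]
    if centers.size == 0:
        centers = np.asarray([0.5 * min(bin_width, max_disp)])
    n_bins = centers.size

    # works[r, b]: NaN where replica r does not reach bin b
    works = np.full((len(ensemble), n_bins), np.nan)
    for r, tr in enumerate(ensemble.trajectories):
        disp = tr.displacement
        cov = centers <= disp[-1]
        works[r, cov] = np.interp(centers[cov], disp, tr.work)

    def profile_for(rows: np.ndarray) -> np.ndarray:
        sub = works[rows]
        out = np.full(n_bins, np.nan)
        for b in range(n_bins):
            col = sub[:, b]
            col = col[~np.isnan(col)]
            if col.size >= min_n:
                out[b] = _ESTIMATOR_FN[estimator](col, kbt)
        defined = ~np.isnan(out)
        if defined.any():
            out[defined] -= out[np.argmax(defined)]
        return out

    all_rows = np.arange(len(ensemble))
    delta_F = profile_for(all_rows)
    n_contributing = np.sum(~np.isnan(works), axis=0)
    undefined = np.isnan(delta_F)
    if undefined.any():
        logger.warning("route %s: %d/%d bins undefined (fewer than %d replicas)",
                       ensemble.route_id, int(undefined.sum()), n_bins, min_n)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    boot = np.full((n_boot, n_bins), np.nan)
    for k in range(n_boot):
        rows = rng.integers(0, len(ensemble), size=len(ensemble))
        boot[k] = profile_for(rows)
    with np.errstate(invalid="ignore"):
        stderr = np.nanstd(boot, axis=0)
    stderr = np.where(np.isnan(delta_F), np.nan, np.nan_to_num(stderr))

    return PMFProfile(route_id=ensemble.route_id, bin_centers=centers,
                      delta_F=delta_F, stderr=stderr,
                      n_contributing=n_contributing, estimator=estimator)


def barrier_height(profile: PMFProfile) -> tuple[float, float]:
    """Largest rise of ΔF above the first defined bin, and where it sits.

    Ties break toward the smaller displacement; a monotone-decreasing
    profile has a barrier of 0 at the first bin.
    """
    defined = profile.defined
    if defined.sum() < 2:
        raise ValueError("profile needs at least 2 defined bins")
    vals = profile.delta_F[defined]
    cents = profile.bin_centers[defined]
    i = int(np.argmax(vals))            # argmax takes the first (smallest s) tie
    barrier = float(vals[i] - vals[0])
    if barrier <= 0.0:
        return 0.0, float(cents[0])
    return barrier, float(cents[i])


def rank_routes(profiles: Sequence[PMFProfile]) -> list[tuple[str, float]]:
    """Routes ordered by ascending barrier; ties lexicographic by route id.

    The first entry is the most probable (lowest-barrier) unbinding route.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    pairs = [(p.route_id, barrier_height(p)[0]) for p in profiles]
    return sorted(pairs, key=lambda rb: (rb[1], rb[0]))
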