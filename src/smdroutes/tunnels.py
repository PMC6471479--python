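"""Grid-based exit-tunnel detection and scoring for sphere-set structures.

A clearance field (distance to the nearest atom surface, i.e. the additively
weighted distance) is sampled on a regular grid over the structure. Voxels
with clearance above a probe radius are traversable; a cheapest path from a
buried start point to the grid boundary is found with Dijkstra's algorithm
under the cost

    cost = Σ step_length / min(clearance, desired_clearance)²,

so wide, short channels are cheap. Each tunnel's priority is exp(−cost),
which lands in (0, 1] and ranks wide/short channels near 1. Distinct exits
are found iteratively: after accepting a path, the free region around it is
blocked and the search repeats until no exit remains.

Tunnels from multiple snapshots can be clustered (average-linkage on
arc-length-resampled paths) and the residues that form each cluster's
bottleneck tabulated. The approach is deliberately simple and grid-based;
it follows the spirit of Voronoi-based tunnel finders without reproducing
any particular tool's cost model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _sp_dijkstra
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform

from .synthetic import SphereStructure

logger = logging.getLogger(__name__)

#: fallback van der Waals radii by element, Å
VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "H": 1.2}
DEFAULT_VDW = 1.7


@dataclass
class TunnelSearchParams:
    grid_spacing: float = 0.25          # Å
    probe_radius: float = 0.9           # minimum traversable clearance, Å
    start_point: tuple[float, float, float] = (0.0, 0.0, 0.0)
    start_max_shift: float = 3.0        # Å the start may move during optimization
    start_desired_clearance: float = 5.0  # clearance clamp, Å
    clustering_threshold: float = 3.5   # Å, path clustering cut and block radius
    max_tunnels: int = 20

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be > 0")
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be > 0")
        if self.grid_spacing > 1.0:
            logger.warning("grid spacing %.2f Å is coarse (> 1 Å); bottleneck "
                           "estimates degrade with the spacing", self.grid_spacing)


@dataclass
class ClearanceGrid:
    """Additively weighted clearance sampled on a regular grid."""

    origin: np.ndarray           # (3,) Å, center of voxel [0,0,0]
    spacing: float
    clearance: np.ndarray        # (nx, ny, nz), Å; negative inside atoms

    def voxel_center(self, idx: Sequence[int]) -> np.ndarray:
        return self.origin + self.spacing * np.asarray(idx, dtype=float)

    def nearest_voxel(self, point: Sequence[float]) -> tuple[int, ...]:
        idx = np.round((np.asarray(point, dtype=float) - self.origin) / self.spacing)
        idx = np.clip(idx, 0, np.asarray(self.clearance.shape) - 1)
        return tuple(int(i) for i in idx)


@dataclass
class Tunnel:
    """One exit path from the start point to open space."""

    tunnel_id: int
    snapshot_id: int
    path: np.ndarray             # (m, 3) voxel centers, start → exit
    clearance: np.ndarray        # clamped clearance per point, Å
    bottleneck_radius: float
    bottleneck_position: np.ndarray
    length: float                # polyline arc length, Å
    avg_radius: float
    cost: float
    priority: float              # exp(−cost) ∈ (0, 1]


@dataclass
class TunnelCluster:
    cluster_id: int
    members: dict[int, Tunnel]   # snapshot_id → best member in that snapshot
    representative: Tunnel
    occurrence_fraction: float
    bottleneck_residues: list[tuple[str, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Clearance field and start optimization
# ---------------------------------------------------------------------------

def clearance_field(structure: SphereStructure,
                    params: TunnelSearchParams) -> ClearanceGrid:
    """Sample min_i(|p − c_i| − r_i) on a grid covering the structure.

    The grid extends past the atom-center bounding box by the largest vdW
    radius plus two probe radii, so the open region just outside the
    structure is traversable. The additively weighted minimum is evaluated
    over the k nearest atom centers (k = 16), exact whenever the vdW radius
    spread is smaller than the kNN distance margin — amply satisfied for
    packed sphere sets.
    """
    lo, hi = structure.bounding_box
    pad = float(structure.radii.max()) + 2.0 * params.probe_radius + params.grid_spacing
    lo = lo - pad
    hi = hi + pad
    shape = np.ceil((hi - lo) / params.grid_spacing).astype(int) + 1
    axes = [lo[d] + params.grid_spacing * np.arange(shape[d]) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    tree = cKDTree(structure.coords)
    k = min(len(structure), 16)
    dist, idx = tree.query(pts, k=k, workers=-1)
    if k == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    clear = (dist - structure.radii[idx]).min(axis=1)
    return ClearanceGrid(origin=lo, spacing=params.grid_spacing,
                         clearance=clear.reshape(tuple(shape)))


def optimize_start(grid: ClearanceGrid, params: TunnelSearchParams) -> np.ndarray:
    """Move the start to the best voxel within ``start_max_shift``.

    "Best" maximizes min(clearance, desired_clearance); among equally good
    voxels the one nearest the original point wins. Raises if nothing within
    reach has clearance >= probe (buried start).
    """
    p0 = np.asarray(params.start_point, dtype=float)
    shape = np.asarray(grid.clearance.shape)
    lo_idx = np.floor((p0 - params.start_max_shift - grid.origin) / grid.spacing).astype(int)
    hi_idx = np.ceil((p0 + params.start_max_shift - grid.origin) / grid.spacing).astype(int)
    lo_idx = np.clip(lo_idx, 0, shape - 1)
    hi_idx = np.clip(hi_idx, 0, shape - 1)
    if np.any(lo_idx > hi_idx):
        raise ValueError("start point lies outside the grid")

    sl = tuple(slice(a, b + 1) for a, b in zip(lo_idx, hi_idx))
    sub = grid.clearance[sl]
    ix, iy, iz = np.meshgrid(*[np.arange(a, b + 1) for a, b in zip(lo_idx, hi_idx)],
                             indexing="ij")
    centers = grid.origin + grid.spacing * np.stack([ix, iy, iz], axis=-1)
    d = np.linalg.norm(centers - p0, axis=-1)
    in_reach = d <= params.start_max_shift
    score = np.minimum(sub, params.start_desired_clearance)
    ok = in_reach & (sub >= params.probe_radius)
    if not ok.any():
        raise ValueError("buried start: no voxel with clearance >= probe radius "
                         f"within {params.start_max_shift} Å of {tuple(p0)}")
    best = score[ok].max()
    cand = ok & (score >= best - 1e-12)
    d_masked = np.where(cand, d, np.inf)
    flat = int(np.argmin(d_masked))
    idx = np.unravel_index(flat, d.shape)
    return centers[idx]


# ---------------------------------------------------------------------------
# Dijkstra on the voxel graph (dimension-agnostic; 2D used by test oracles)
# ---------------------------------------------------------------------------

def voxel_dijkstra(clearance: np.ndarray, spacing: float,
                   start_idx: tuple[int, ...], probe_radius: float,
                   desired_clearance: float
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Single-source cheapest paths over the free-voxel graph.

    Voxels with clearance >= probe_radius are nodes; neighbors (full
    3^d − 1 connectivity) are joined by edges of cost
    step_length / min(½(c_u + c_v), desired_clearance)². Returns
    (cost, predecessor, compact_id) arrays on the full grid, with
    unreachable/blocked voxels at inf / −1.
    """
    free = clearance >= probe_radius
    if not free[start_idx]:
        raise ValueError("start voxel is not traversable")
    ndim = clearance.ndim
    comp = np.full(clearance.shape, -1, dtype=np.int64)
    n_free = int(free.sum())
    comp[free] = np.arange(n_free)

    rows, cols, weights = [], [], []
    offsets = [off for off in np.ndindex(*(3,) * ndim)
               if any(o != 1 for o in off)]
    offsets = [tuple(o - 1 for o in off) for off in offsets]
    # keep one of each ± pair; edges are added in both directions below
    offsets = [off for off in offsets if off > tuple(-o for o in off)]

    for off in offsets:
        src_sl, dst_sl = [], []
        for o in off:
            if o == 0:
                src_sl.append(slice(None))
                dst_sl.append(slice(None))
            elif o > 0:
                src_sl.append(slice(None, -o))
                dst_sl.append(slice(o, None))
            else:
                src_sl.append(slice(-o, None))
                dst_sl.append(slice(None, o))
        a = comp[tuple(src_sl)].ravel()
        b = comp[tuple(dst_sl)].ravel()
        ca = clearance[tuple(src_sl)].ravel()
        cb = clearance[tuple(dst_sl)].ravel()
        valid = (a >= 0) & (b >= 0)
        if not valid.any():
            continue
        step = spacing * math.sqrt(sum(o * o for o in off))
        cmid = np.minimum(0.5 * (ca[valid] + cb[valid]), desired_clearance)
        w = step / (cmid * cmid)
        rows.append(a[valid]); cols.append(b[valid]); weights.append(w)
        rows.append(b[valid]); cols.append(a[valid]); weights.append(w)

    graph = coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_free, n_free)).tocsr()
    cost_c, pred_c = _sp_dijkstra(graph, directed=True,
                                  indices=int(comp[start_idx]),
                                  return_predecessors=True)
    cost = np.full(clearance.shape, np.inf)
    cost[free] = cost_c
    pred = np.full(clearance.shape, -1, dtype=np.int64)
    pred[free] = pred_c
    return cost, pred, comp


def _reconstruct(pred: np.ndarray, comp: np.ndarray,
                 end_idx: tuple[int, ...]) -> list[tuple[int, ...]]:
    lookup = {int(comp[tuple(i)]): tuple(i) for i in np.argwhere(comp >= 0)}
    path = [end_idx]
    node = int(comp[end_idx])
    while True:
        p = int(pred[path[-1]])
        if p < 0:
            break
        nxt = lookup[p]
        path.append(nxt)
        node = p
    return path[::-1]


# ---------------------------------------------------------------------------
# Tunnel search
# ---------------------------------------------------------------------------

def _boundary_mask(shape: tuple[int, ...]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for d in range(len(shape)):
        sl_lo = [slice(None)] * len(shape)
        sl_hi = [slice(None)] * len(shape)
        sl_lo[d] = 0
        sl_hi[d] = shape[d] - 1
        mask[tuple(sl_lo)] = True
        mask[tuple(sl_hi)] = True
    return mask


def find_tunnels(structure: SphereStructure, params: TunnelSearchParams,
                 *, snapshot_id: int = 0) -> list[Tunnel]:
    """All distinct exit tunnels from the (optimized) start point.

    Iterative search: accept the globally cheapest start→boundary path,
    block the free region within the clustering threshold of it (never
    within that radius of the start itself), repeat. Returns tunnels sorted
    by priority, highest first; a sealed cavity gives an empty list.
    """
    grid = clearance_field(structure, params)
    start_xyz = optimize_start(grid, params)
    start_idx = grid.nearest_voxel(start_xyz)
    boundary = _boundary_mask(grid.clearance.shape)
    desired = params.start_desired_clearance

    clearance = grid.clearance.copy()
    tunnels: list[Tunnel] = []
    blocked = np.zeros(clearance.shape, dtype=bool)

    for tid in range(params.max_tunnels):
        work = np.where(blocked, -np.inf, clearance)
        if work[start_idx] < params.probe_radius:
            break
        cost, pred, comp = voxel_dijkstra(work, grid.spacing, start_idx,
                                          params.probe_radius, desired)
        exit_costs = np.where(boundary, cost, np.inf)
        best_flat = int(np.argmin(exit_costs))
        best_idx = np.unravel_index(best_flat, clearance.shape)
        if not np.isfinite(exit_costs[best_idx]):
            break

        idx_path = _reconstruct(pred, comp, tuple(best_idx))
        pts = np.asarray([grid.voxel_center(i) for i in idx_path])
        clear_raw = np.asarray([clearance[i] for i in idx_path])
        clear_clamped = np.minimum(clear_raw, desired)
        node_cost = np.asarray([cost[i] for i in idx_path])

        # report the tunnel up to where it reaches open space past the throat
        i_bottle = int(np.argmin(clear_clamped))
        cut = len(pts)
        for j in range(i_bottle + 1, len(pts)):
            if clear_raw[j] >= desired:
                cut = j + 1
                break
        pts_t = pts[:cut]
        clear_t = clear_clamped[:cut]
        seg = np.linalg.norm(np.diff(pts_t, axis=0), axis=1)
        length = float(seg.sum())
        tcost = float(node_cost[cut - 1])
        tunnels.append(Tunnel(
            tunnel_id=tid, snapshot_id=snapshot_id,
            path=pts_t, clearance=clear_t,
            bottleneck_radius=float(clear_t.min()),
            bottleneck_position=pts_t[int(np.argmin(clear_t))].copy(),
            length=length, avg_radius=float(clear_t.mean()),
            cost=tcost, priority=float(math.exp(-tcost))))

        # block the accepted channel so the next search finds a different
        # exit; path points near the start stay out of it so the remaining
        # cavity keeps its corridors to other channels
        block_r = np.maximum(params.clustering_threshold,
                             clear_clamped + grid.spacing)
        d_path_start = np.linalg.norm(pts - np.asarray(start_xyz)[None, :], axis=1)
        centers_ok = d_path_start > params.clustering_threshold
        if not centers_ok.any():
            break
        pts_c = pts[centers_ok]
        block_r = block_r[centers_ok]
        free_idx = np.argwhere(~blocked & (clearance >= params.probe_radius))
        free_xyz = grid.origin + grid.spacing * free_idx
        ptree = cKDTree(pts_c)
        kq = min(len(pts_c), 8)
        d_near, j_near = ptree.query(free_xyz, k=kq, workers=-1)
        if kq == 1:
            d_near = d_near[:, None]
            j_near = j_near[:, None]
        hit = (d_near <= block_r[j_near]).any(axis=1)
        d_start = np.linalg.norm(free_xyz - np.asarray(start_xyz), axis=1)
        hit &= d_start > params.clustering_threshold
        blocked[tuple(free_idx[hit].T)] = True

    # safety net: drop near-duplicate paths the blocking left behind
    unique: list[Tunnel] = []
    for t in sorted(tunnels, key=lambda t: -t.priority):
        rt = resample_path(t.path)
        if all(_path_distance(rt, resample_path(u.path)) > params.clustering_threshold
               for u in unique):
            unique.append(t)
    tunnels = unique
    for new_id, t in enumerate(tunnels):
        t.tunnel_id = new_id
    logger.info("snapshot %d: %d tunnel(s) found", snapshot_id, len(tunnels))
    return tunnels


# ---------------------------------------------------------------------------
# Clustering across snapshots and bottleneck residues
# ---------------------------------------------------------------------------

def resample_path(path: np.ndarray, n_points: int = 64) -> np.ndarray:
    """Resample a polyline to ``n_points`` equally spaced in arc length."""
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0.0:
        return np.repeat(path[:1], n_points, axis=0)
    target = np.linspace(0.0, s[-1], n_points)
    return np.column_stack([np.interp(target, s, path[:, d]) for d in range(3)])


def _path_distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean(np.linalg.norm(a - b, axis=1)))


def cluster_tunnels(per_snapshot_tunnels: Sequence[Sequence[Tunnel]],
                    params: TunnelSearchParams) -> list[TunnelCluster]:
    """Average-linkage clustering of tunnels across snapshots.

    Distance between two tunnels is the mean pointwise distance between
    their arc-length-resampled paths (64 points); the dendrogram is cut at
    the clustering threshold. Each cluster's representative is its
    highest-priority member; occurrence is the fraction of snapshots with at
    least one member.
    """
    n_snapshots = len(per_snapshot_tunnels)
    if n_snapshots < 1:
        raise ValueError("need at least one snapshot")
    flat: list[Tunnel] = [t for snap in per_snapshot_tunnels for t in snap]
    if not flat:
        return []

    resampled = [resample_path(t.path) for t in flat]
    if len(flat) == 1:
        labels = np.asarray([1])
    else:
        m = len(flat)
        dm = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                dm[i, j] = dm[j, i] = _path_distance(resampled[i], resampled[j])
        labels = fcluster(linkage(squareform(dm), method="average"),
                          t=params.clustering_threshold, criterion="distance")

    clusters: list[TunnelCluster] = []
    for cid in sorted(set(labels)):
        members_all = [t for t, lab in zip(flat, labels) if lab == cid]
        by_snap: dict[int, Tunnel] = {}
        for t in members_all:
            cur = by_snap.get(t.snapshot_id)
            if cur is None or t.priority > cur.priority:
                by_snap[t.snapshot_id] = t
        rep = max(members_all, key=lambda t: t.priority)
        clusters.append(TunnelCluster(
            cluster_id=len(clusters),
            members=by_snap, representative=rep,
            occurrence_fraction=len(by_snap) / n_snapshots))
    clusters.sort(key=lambda c: -c.representative.priority)
    for new_id, c in enumerate(clusters):
        c.cluster_id = new_id
    return clusters


def bottleneck_residue_table(cluster: TunnelCluster, structure: SphereStructure,
                             shell_tolerance: float = 0.5
                             ) -> list[tuple[str, float]]:
    """Residues whose atom surfaces line the cluster's bottlenecks.

    For each member tunnel, every atom whose surface lies within
    ``shell_tolerance`` Å of the bottleneck clearance sphere contributes its
    residue once. Frequencies are counts divided by the number of members,
    sorted descending (ties alphabetical), and stored on the cluster.
    """
    counts: dict[str, int] = {}
    members = list(cluster.members.values())
    for t in members:
        d = np.linalg.norm(structure.coords - t.bottleneck_position[None, :], axis=1)
        gap = np.abs(d - structure.radii - t.bottleneck_radius)
        residues = {structure.residue_label(i)
                    for i in np.flatnonzero(gap <= shell_tolerance)}
        for r in residues:
            counts[r] = counts.get(r, 0) + 1
    table = sorted(((res, c / len(members)) for res, c in counts.items()),
                   key=lambda rf: (-rf[1], rf[0]))
    cluster.bottleneck_residues = table
    return table
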