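"""Trajectory metrics: Kabsch superposition, RMSD, RMSF, atom-pair distances.

Superposition uses the least-squares optimal proper rotation (reflections
corrected), so RMSD/RMSF are invariant under arbitrary rigid motions of the
input frames. RMSF is computed about an iterated mean structure (two passes
of superpose-then-average), a common convention. Pair distances are internal
coordinates and are computed without superposition.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass
class FrameSeries:
    """Coordinate frames for a fixed atom set."""

    names: list[str]
    resids: list[int]
    frames: np.ndarray          # (n_frames, n_atoms, 3) Å
    times: np.ndarray           # ps

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("need at least one frame")
        n_atoms = self.frames.shape[1]
        if len(self.names) != n_atoms or len(self.resids) != n_atoms:
            raise ValueError("atom labels must match the frame atom count")
        if len(self.times) != self.frames.shape[0]:
            raise ValueError("one time per frame required")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def select(self, name_glob: str = "*",
               residue_range: tuple[int, int] | None = None) -> np.ndarray:
        """Atom indices matching an atom-name glob and residue range.

        ``name_glob="backbone"`` selects N, CA, C, O.
        """
        if name_glob == "backbone":
            mask = np.asarray([n in BACKBONE_NAMES for n in self.names])
        else:
            mask = np.asarray([fnmatch.fnmatch(n, name_glob) for n in self.names])
        if residue_range is not None:
            lo, hi = residue_range
            mask &= np.asarray([lo <= r <= hi for r in self.resids])
        return np.flatnonzero(mask)

    def atom_index(self, name: str, resid: int | None = None) -> int:
        """The unique atom with this name (and residue id, if given)."""
        hits = [i for i, (n, r) in enumerate(zip(self.names, self.resids))
                if n == name and (resid is None or r == resid)]
        if len(hits) == 1:
            return hits[0]
        if not hits:
            cands = sorted(set(self.names))
            raise KeyError(f"no atom named {name!r}"
                           + (f" in residue {resid}" if resid is not None else "")
                           + f"; atom names present: {cands[:20]}")
        raise KeyError(f"atom name {name!r} is ambiguous (residues "
                       f"{[self.resids[i] for i in hits]}); pass a residue id")


def superpose(mobile: np.ndarray, reference: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation matrix R, translation t, rmsd) with the convention
    ``aligned = mobile @ R.T + t``. The rotation is always proper
    (det R = +1). Needs >= 3 non-collinear atoms.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n, 3)")
    n = mob.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 atoms")
    mc = mob - mob.mean(axis=0)
    rc = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(np.vstack([mc, rc]), tol=1e-10) < 2:
        raise ValueError("atom sets are collinear; superposition is degenerate")
    rot, _ = Rotation.align_vectors(rc, mc)
    R = rot.as_matrix()
    t = ref.mean(axis=0) - mob.mean(axis=0) @ R.T
    dev = mc @ R.T - rc
    rmsd = float(np.sqrt(np.mean(np.sum(dev * dev, axis=1))))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return coords @ R.T + t


def rmsd_series(series: FrameSeries, reference_frame: int = 0,
                selection: np.ndarray | None = None) -> np.ndarray:
    """Per-frame RMSD of the selection after superposition onto a reference
    frame."""
    if not -series.n_frames <= reference_frame < series.n_frames:
        raise IndexError(f"reference frame {reference_frame} out of range")
    sel = np.arange(series.n_atoms) if selection is None else np.asarray(selection)
    if sel.size == 0:
        raise ValueError("selection is empty")
    ref = series.frames[reference_frame][sel]
    out = np.empty(series.n_frames)
    for i in range(series.n_frames):
        _, _, out[i] = superpose(series.frames[i][sel], ref)
    return out


def rmsf_per_atom(series: FrameSeries,
                  selection: np.ndarray | None = None,
                  n_iterations: int = 2) -> np.ndarray:
    """Per-atom RMSF about the iterated mean structure.

    Frames are superposed onto the running mean structure for
    ``n_iterations`` passes (seeded with the first frame); RMSF_i is the
    root-mean-square distance of atom i from its final mean position.
    """
    if series.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    sel = np.arange(series.n_atoms) if selection is None else np.asarray(selection)
    if sel.size == 0:
        raise ValueError("selection is empty")
    coords = series.frames[:, sel, :].copy()
    ref = coords[0]
    for _ in range(n_iterations):
        for i in range(coords.shape[0]):
            R, t, _ = superpose(coords[i], ref)
            coords[i] = apply_transform(coords[i], R, t)
        ref = coords.mean(axis=0)
    dev = coords - ref[None, :, :]
    return np.sqrt(np.mean(np.sum(dev * dev, axis=2), axis=0))


def pair_distance_series(series: FrameSeries, atom_a: str | int,
                         atom_b: str | int, *,
                         resid_a: int | None = None,
                         resid_b: int | None = None) -> np.ndarray:
    """Euclidean distance between two atoms per frame (no superposition)."""
    ia = atom_a if isinstance(atom_a, (int, np.integer)) else series.atom_index(atom_a, resid_a)
    ib = atom_b if isinstance(atom_b, (int, np.integer)) else series.atom_index(atom_b, resid_b)
    diff = series.frames[:, ia, :] - series.frames[:, ib, :]
    return np.linalg.norm(diff, axis=1)
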