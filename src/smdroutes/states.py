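"""Decomposition of a PMF profile into unbinding states.

Interior local maxima with topographic prominence above a threshold become
transition states; the minima between consecutive transition states become
metastable states; the first bin is the bound state (ΔF = 0) and the last
the unbound terminus. With a constant-velocity protocol each state maps to
the pulling time displacement/v at which the restraint passes it.

Labels follow the P/A/B/C/…/F lettering convention for unbinding pathways
(P = bound pocket state, F = free/unbound terminus, interior states lettered
in displacement order); they are cosmetic — the ``kind`` field is the
contract.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .pmf import PMFProfile
from .synthetic import PullingProtocol

KINDS = ("bound", "transition", "metastable", "unbound")


@dataclass(frozen=True)
class State:
    label: str
    kind: str
    displacement: float      # Å
    delta_F: float           # kcal/mol
    time: float | None = None  # ps; filled by state_times


@dataclass
class StateAnnotation:
    """Ordered states of one PMF profile."""

    route_id: str
    states: list[State]
    prominence_threshold: float

    def __post_init__(self) -> None:
        kinds = [s.kind for s in self.states]
        if kinds[0] != "bound" or kinds[-1] != "unbound":
            raise ValueError("states must start bound and end unbound")
        if self.states[0].delta_F != 0.0:
            raise ValueError("bound state must sit at delta_F = 0")
        # bound (transition metastable)* transition? unbound
        interior = kinds[1:-1]
        expected = "transition"
        for k in interior:
            if k != expected:
                raise ValueError(f"states do not alternate: {kinds}")
            expected = "metastable" if expected == "transition" else "transition"

    @property
    def transition_states(self) -> list[State]:
        return [s for s in self.states if s.kind == "transition"]

    @property
    def metastable_states(self) -> list[State]:
        return [s for s in self.states if s.kind == "metastable"]


def _interior_letters(n: int) -> list[str]:
    """A, B, C, … skipping the reserved endpoint letters P and F."""
    letters = [c for c in "ABCDEGHIJKLMNOQRSTUVWXYZ"]
    return letters[:n]


def find_states(profile: PMFProfile, prominence: float = 1.0) -> StateAnnotation:
    """Label bound/transition/metastable/unbound states of a PMF profile.

    Runs of equal values (plateaus) collapse to their midpoint bin. Peaks
    are accepted when their topographic prominence within the defined part
    of the profile reaches ``prominence`` kcal/mol.
    """
    if prominence <= 0:
        raise ValueError("prominence must be > 0")
    defined = profile.defined
    if defined.sum() < 3:
        raise ValueError("profile needs at least 3 defined bins")
    y = profile.delta_F[defined]
    x = profile.bin_centers[defined]
    y = y - y[0]

    peaks, props = find_peaks(y, prominence=prominence, plateau_size=1)
    # collapse plateaus to their midpoint bin
    peak_idx = [int(round(0.5 * (le + re)))
                for le, re in zip(props["left_edges"], props["right_edges"])]

    states: list[State] = [State("P", "bound", float(x[0]), 0.0)]
    letters = iter(_interior_letters(2 * len(peak_idx)))
    prev = None
    for p in peak_idx:
        if prev is not None:
            seg = slice(prev + 1, p)
            vi = prev + 1 + _plateau_argmin(y[seg])
            states.append(State(next(letters), "metastable", float(x[vi]), float(y[vi])))
        states.append(State(next(letters), "transition", float(x[p]), float(y[p])))
        prev = p
    states.append(State("F", "unbound", float(x[-1]), float(y[-1])))
    return StateAnnotation(route_id=profile.route_id, states=states,
                           prominence_threshold=prominence)


def _plateau_argmin(seg: np.ndarray) -> int:
    """Index of the minimum; a run of equal minima collapses to its middle."""
    m = seg.min()
    idx = np.flatnonzero(seg == m)
    return int(idx[(len(idx) - 1) // 2])


def state_times(annotation: StateAnnotation,
                protocol: PullingProtocol) -> StateAnnotation:
    """Attach the pulling time displacement/v to every state."""
    if protocol.velocity == 0:
        raise ValueError("state times are undefined for v = 0")
    timed = [replace(s, time=s.displacement / protocol.velocity)
             for s in annotation.states]
    return StateAnnotation(route_id=annotation.route_id, states=timed,
                           prominence_threshold=annotation.prominence_threshold)
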