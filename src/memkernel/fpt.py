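"""Mean first-passage times from discretized trajectories.

On discretized data a crossing between two frames is unobservable, so a
passage is counted at the first frame at-or-beyond the target. This
makes MFPTs computed from a reference trajectory and from a GLE
simulation directly comparable when both use the same discretization.

Event definition (renewal convention): an event starts whenever the
trajectory enters the start region [start - tol, start + tol] while no
event is in progress; within the event, the first-passage time to each
target is the time of the first frame at-or-beyond that target; the
event completes once the farthest target has been reached (or the
trajectory ends), after which a new event requires re-entering the
start region. Entries that occur while an event is in progress are
ignored, which prevents double counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .timeseries import Trajectory

__all__ = ["FPTProfile", "mfpt", "fold_unfold_times"]


@dataclass
class FPTProfile:
    """MFPT from a start region to an ordered sequence of targets.

    ``tau_mfp`` holds NaN for targets with zero completed events (a
    missing value, deliberately distinct from zero).
    """

    start: float
    targets: np.ndarray
    tau_mfp: np.ndarray
    n_events: np.ndarray
    direction: str

    def save_tsv(self, path: str) -> None:
        np.savetxt(
            path,
            np.column_stack([self.targets, self.tau_mfp, self.n_events]),
            delimiter="\t",
            header=f"target_nm\ttau_mfp_ps\tn_events (start={self.start} nm)",
        )


def mfpt(
    traj: Trajectory,
    start: float,
    targets: Sequence[float],
    start_tol: float,
    direction: str = "profile",
) -> FPTProfile:
    """Mean first-passage times from ``start`` to each of ``targets``.

    ``targets`` must lie on one side of the start region and are
    processed in order of increasing distance from ``start``. ``start_tol``
    sets the half-width of the start region (a natural default is one
    PMF bin width).
    """
    x = traj.positions
    targets = np.asarray(targets, dtype=float)
    if targets.size == 0:
        raise ValueError("need at least one target")
    above = targets > start
    if not (above.all() or (~above).all()):
        raise ValueError("targets must all lie on one side of the start position")
    sign = 1.0 if above.all() else -1.0
    order = np.argsort(sign * targets)
    tgt_sorted = targets[order]

    in_region = np.abs(x - start) <= start_tol
    # entries: first frame, or an in-region frame preceded by an out-of-region frame
    entry_mask = in_region.copy()
    entry_mask[1:] &= ~in_region[:-1]
    entries = np.nonzero(entry_mask)[0]
    if entries.size == 0:
        raise ValueError("trajectory never visits the start region")

    # frame indices at-or-beyond each target
    beyond_idx = [np.nonzero(sign * x >= sign * t)[0] for t in tgt_sorted]

    n_t = tgt_sorted.size
    total = np.zeros(n_t)
    count = np.zeros(n_t, dtype=int)
    e = 0
    while e < entries.size:
        s = entries[e]
        completed_at = None
        for it in range(n_t):
            idx = beyond_idx[it]
            pos = np.searchsorted(idx, s)
            if pos < idx.size:
                total[it] += (idx[pos] - s) * traj.dt
                count[it] += 1
                completed_at = idx[pos]
            else:
                break
        if completed_at is None:
            # nothing reached after this entry; no later entry will do better
            break
        # re-arm: next event starts at the first entry after completion
        e = int(np.searchsorted(entries, completed_at + 1))

    tau = np.full(n_t, np.nan)
    nonzero = count > 0
    tau[nonzero] = total[nonzero] / count[nonzero]

    # undo the distance ordering so output matches the caller's order
    inv = np.empty_like(order)
    inv[order] = np.arange(n_t)
    return FPTProfile(
        start=start,
        targets=targets,
        tau_mfp=tau[inv],
        n_events=count[inv],
        direction=direction,
    )


def fold_unfold_times(
    traj: Trajectory,
    folded: float,
    unfolded: float,
    start_tol: float,
):
    """Mean first-passage times between two metastable positions.

    Returns ``(tau_fold, tau_unfold, n_fold, n_unfold)``: the folding
    time is the MFPT from the unfolded position to the folded one, and
    vice versa.
    """
    fold = mfpt(traj, start=unfolded, targets=[folded], start_tol=start_tol, direction="folding")
    unfold = mfpt(traj, start=folded, targets=[unfolded], start_tol=start_tol, direction="unfolding")
    return (
        float(fold.tau_mfp[0]),
        float(unfold.tau_mfp[0]),
        int(fold.n_events[0]),
        int(unfold.n_events[0]),
    )
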