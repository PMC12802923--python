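"""Sister-locus distance trajectories and spindle-length series.

In live-cell imaging of a tetO/TetR-GFP labelled locus, each timepoint yields
zero, one, or two resolvable GFP dots.  One dot means the sisters are
co-localized (distance recorded as 0); two dots give a 3-D Euclidean
separation in µm.  Per-cell trajectories are classified by the separation
profile over the time-lapse:

* **not_separated** — the distance never exceeds the separation threshold
  (default 2 µm);
* **breathing** — the distance exceeds the threshold at some point but later
  returns to (effectively) zero, i.e. at or below a rejoin tolerance
  ``eps`` (default 0.25 µm, two dots being unresolvable at diffraction
  scale);
* **separated** — the distance exceeds the threshold and never returns to
  zero afterwards.

Spindle length series are the same geometry applied to two spindle-pole
endpoints, summarized per cell as mean and maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DotTrajectory",
    "TrajectoryCall",
    "distance_series",
    "classify_trajectory",
    "spindle_length_series",
]

SEPARATION_THRESHOLD_UM = 2.0
REJOIN_EPS_UM = 0.25


@dataclass
class DotTrajectory:
    """Time series of two 3-D locus positions for one cell.

    ``pos1``/``pos2`` have shape (T, 3) in µm; a row of NaN means that dot was
    unresolved at that timepoint.  One resolved dot means co-localized sisters
    (distance 0); both missing drops the timepoint.
    """

    cell: str
    t_min: np.ndarray
    pos1: np.ndarray
    pos2: np.ndarray

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.pos1 = np.asarray(self.pos1, dtype=float).reshape(-1, 3)
        self.pos2 = np.asarray(self.pos2, dtype=float).reshape(-1, 3)
        if not (len(self.t_min) == len(self.pos1) == len(self.pos2)):
            raise ValueError("timepoints and positions disagree in length")
        if np.any(np.diff(self.t_min) <= 0):
            raise ValueError("timepoints must be strictly increasing")


@dataclass
class TrajectoryCall:
    cell: str
    klass: str  # not_separated | breathing | separated
    max_distance_um: float
    first_crossing_min: float | None


def distance_series(traj: DotTrajectory) -> tuple[np.ndarray, np.ndarray]:
    """Per-timepoint 3-D Euclidean distance (µm).

    Returns ``(t_min, distances)`` after dropping timepoints where both dots
    are missing (with a warning).  Single-dot timepoints score distance 0.
    """
    m1 = np.isnan(traj.pos1).any(axis=1)
    m2 = np.isnan(traj.pos2).any(axis=1)
    both_missing = m1 & m2
    if both_missing.any():
        warnings.warn(
            f"cell {traj.cell}: dropping {int(both_missing.sum())} timepoint(s) "
            "with no resolvable dot",
            stacklevel=2,
        )
    keep = ~both_missing
    d = np.linalg.norm(traj.pos1[keep] - traj.pos2[keep], axis=1)
    d = np.where(np.isnan(d), 0.0, d)  # one dot unresolved -> co-localized
    return traj.t_min[keep], d


def classify_trajectory(
    distances: np.ndarray,
    t_min: np.ndarray | None = None,
    sep_thr: float = SEPARATION_THRESHOLD_UM,
    eps: float = REJOIN_EPS_UM,
    cell: str = "",
) -> TrajectoryCall:
    """Apply the three-category separation rule to a distance series."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance series (all timepoints missing?)")
    if d.size < 2:
        raise ValueError("need at least 2 timepoints to classify")
    t = np.arange(d.size, dtype=float) if t_min is None else np.asarray(t_min, dtype=float)
    over = d > sep_thr
    max_d = float(d.max())
    if not over.any():
        return TrajectoryCall(cell, "not_separated", max_d, None)
    first = int(np.argmax(over))
    rejoined = np.any(d[first + 1 :] <= eps)
    klass = "breathing" if rejoined else "separated"
    return TrajectoryCall(cell, klass, max_d, float(t[first]))


def spindle_length_series(
    t_min: np.ndarray, pole1: np.ndarray, pole2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Spindle length per timepoint plus per-cell mean and max.

    Timepoints with a missing pole are dropped.  Returns
    ``(t_kept, lengths_um, mean_um, max_um)``.
    """
    t_min = np.asarray(t_min, dtype=float)
    pole1 = np.asarray(pole1, dtype=float).reshape(-1, 3)
    pole2 = np.asarray(pole2, dtype=float).reshape(-1, 3)
    missing = np.isnan(pole1).any(axis=1) | np.isnan(pole2).any(axis=1)
    keep = ~missing
    if not keep.any():
        raise ValueError("no timepoint has both spindle poles")
    lengths = np.linalg.norm(pole1[keep] - pole2[keep], axis=1)
    return t_min[keep], lengths, float(lengths.mean()), float(lengths.max())
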