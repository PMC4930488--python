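"""Quantification operators for image-derived measurements.

These mirror the measurements made on segmented microscopy data and
tracked high-speed movies: per-cell principal deformation between a
tense (attached) and relaxed (excised) state, orientation statistics of
cortical-microtubule / cellulose-fibril segments, and speed extraction
from tracked points.  No image processing happens here — the inputs are
vertex and segment tables (surface extraction and fibril detection are
upstream, out of scope).

Conventions: the fruit's longitudinal axis is +x; angles are measured
in degrees from that axis; positions in μm unless noted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CellOutlinePair", "DeformationSummary", "OrientationSet",
    "cell_deformation", "tension_map", "orientation_stats", "track_speeds",
]


@dataclass
class CellOutlinePair:
    """Matched pre/post vertex lists of one cell outline (2D, μm)."""

    cell_id: int
    pre: np.ndarray               # (k, 2)
    post: np.ndarray              # (k, 2)

    def __post_init__(self):
        self.pre = np.asarray(self.pre, dtype=float)
        self.post = np.asarray(self.post, dtype=float)
        if self.pre.shape != self.post.shape or self.pre.ndim != 2 \
                or self.pre.shape[1] != 2:
            raise ValueError("pre/post must be matched (k, 2) arrays")
        if len(self.pre) < 3:
            raise ValueError("need at least 3 matched vertices")


@dataclass(frozen=True)
class DeformationSummary:
    """Principal stretches and directions of one cell's deformation."""

    cell_id: int
    lambda1: float                # major principal stretch
    lambda2: float                # minor principal stretch
    direction1_deg: float         # of lambda1, degrees from fruit axis
    direction2_deg: float

    @property
    def shrinkage_percent(self) -> tuple[float, float]:
        """(1 - lambda) * 100 per principal direction."""
        return ((1.0 - self.lambda1) * 100.0, (1.0 - self.lambda2) * 100.0)

    @property
    def max_shrinkage_percent(self) -> float:
        return (1.0 - min(self.lambda1, self.lambda2)) * 100.0

    @property
    def max_shrinkage_direction_deg(self) -> float:
        """Direction of maximal shrinkage (the minor stretch), folded to
        [0°, 90°] relative to the fruit axis."""
        d = self.direction2_deg % 180.0
        return d if d <= 90.0 else 180.0 - d


@dataclass
class OrientationSet:
    """Oriented segments of one or more cells: angle (deg) + weight."""

    angles_deg: np.ndarray
    weights: np.ndarray = None

    def __post_init__(self):
        self.angles_deg = np.asarray(self.angles_deg, dtype=float) % 180.0
        if self.weights is None:
            self.weights = np.ones_like(self.angles_deg)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if self.weights.shape != self.angles_deg.shape:
            raise ValueError("angles and weights lengths differ")


def cell_deformation(pair: CellOutlinePair) -> DeformationSummary:
    """Best-fit affine deformation gradient and its polar decomposition.

    Fits ``post - mean = F (pre - mean)`` by least squares on the
    centered vertices, then extracts the right stretch tensor
    ``U = sqrt(F^T F)``: its eigenvalues are the principal stretches,
    its eigenvectors (in the pre/material frame) the principal
    directions.
    """
    P = pair.pre - pair.pre.mean(axis=0)
    Q = pair.post - pair.post.mean(axis=0)
    A = P.T @ P
    if np.linalg.matrix_rank(A, tol=1e-10 * np.trace(A)) < 2:
        raise ValueError(f"cell {pair.cell_id}: degenerate (collinear) "
                         "vertices")
    F = np.linalg.solve(A, P.T @ Q).T
    C = F.T @ F
    w, V = np.linalg.eigh(C)
    lam = np.sqrt(np.maximum(w, 0.0))
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    V = V[:, order]
    dirs = np.degrees(np.arctan2(V[1], V[0])) % 180.0
    return DeformationSummary(pair.cell_id, float(lam[0]), float(lam[1]),
                              float(dirs[0]), float(dirs[1]))


def tension_map(pairs: list[CellOutlinePair]) -> tuple[pd.DataFrame, str]:
    """Per-cell shrinkage table plus the dominant tension class.

    Shrinkage direction per cell is the direction of maximal shrinkage
    (folded to [0°, 90°] from the fruit axis).  The map is classed
    ``"longitudinal"`` if the median direction is below 45°, else
    ``"lateral"`` — the developmental switch from seed-driven lateral
    tension to the longitudinal tension that drives coiling.
    """
    if not pairs:
        raise ValueError("need at least one outline pair")
    rows = []
    for pair in pairs:
        s = cell_deformation(pair)
        rows.append((pair.cell_id, s.max_shrinkage_percent,
                     s.max_shrinkage_direction_deg))
    table = pd.DataFrame(rows, columns=["cell_id", "shrinkage_percent",
                                        "direction_deg"])
    cls = ("longitudinal"
           if float(table["direction_deg"].median()) < 45.0 else "lateral")
    return table, cls


def orientation_stats(segments: OrientationSet, fruit_axis_deg: float = 0.0,
                      bins: tuple = ((0.0, 30.0), (30.0, 45.0),
                                     (45.0, 90.0))) -> dict:
    """Weighted orientation histogram and principal orientation.

    Angles are taken relative to the fruit axis and folded to [0°, 90°];
    the default bins mirror the longitudinal (0–30°) / transverse
    (45–90°) classification.  The principal orientation is the
    structure-tensor (doubled-angle vector) mean; it is flagged
    undefined for an isotropic set (vanishing doubled-angle resultant).
    """
    rel = (segments.angles_deg - fruit_axis_deg) % 180.0
    folded = np.where(rel > 90.0, 180.0 - rel, rel)
    w = segments.weights
    wsum = w.sum()
    if wsum == 0:
        raise ValueError("all weights are zero")
    hist = {}
    for lo, hi in bins:
        last = hi >= max(h for _, h in bins)
        sel = (folded >= lo) & ((folded <= hi) if last else (folded < hi))
        hist[f"[{lo:g}-{hi:g})" if not last else f"[{lo:g}-{hi:g}]"] = \
            float(w[sel].sum() / wsum)
    # structure tensor: resultant of doubled angles
    phi2 = np.radians(2.0 * rel)
    cx = float(np.sum(w * np.cos(phi2)) / wsum)
    sx = float(np.sum(w * np.sin(phi2)) / wsum)
    R = np.hypot(cx, sx)
    if R < 1e-9:
        principal = None
        iso = True
    else:
        principal = (np.degrees(np.arctan2(sx, cx)) / 2.0) % 180.0
        principal = principal if principal <= 90.0 else 180.0 - principal
        iso = False
    cls = None
    if principal is not None:
        cls = ("longitudinal" if principal < 30.0
               else "transverse" if principal >= 45.0 else "intermediate")
    return {"histogram": hist, "principal_deg": principal,
            "isotropic": iso, "anisotropy": R, "class": cls}


def track_speeds(tracks: pd.DataFrame, fps: float,
                 release_frame: dict | None = None) -> dict:
    """Central-difference speeds of tracked points.

    ``tracks`` has columns (point_id, frame, x, y) with positions in mm;
    speeds are returned in m/s.  ``release_frame`` optionally maps point
    id -> first frame after release; the launch speed of a point is its
    speed at that frame (default: its maximum speed).
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    required = {"point_id", "frame", "x", "y"}
    if not required <= set(tracks.columns):
        raise ValueError(f"tracks table needs columns {sorted(required)}")
    if tracks.duplicated(subset=["point_id", "frame"]).any():
        raise ValueError("duplicate (point, frame) rows")
    dt = 1.0 / fps
    per_point = {}
    launch = {}
    for pid, grp in tracks.sort_values("frame").groupby("point_id"):
        if len(grp) < 2:
            raise ValueError(f"point {pid} has fewer than 2 frames")
        xy = grp[["x", "y"]].to_numpy() * 1e-3    # mm -> m
        frames = grp["frame"].to_numpy()
        v = np.gradient(xy, dt, axis=0)
        speed = np.linalg.norm(v, axis=1)
        per_point[pid] = pd.DataFrame(
            {"frame": frames, "speed": speed, "vx": v[:, 0], "vy": v[:, 1]})
        if release_frame and pid in release_frame:
            idx = int(np.searchsorted(frames, release_frame[pid]))
            idx = min(idx, len(speed) - 1)
            launch[pid] = float(speed[idx])
        else:
            launch[pid] = float(speed.max())
    vals = np.array(list(launch.values()))
    return {"speeds": per_point, "launch_speed": launch,
            "mean": float(vals.mean()), "sd": float(vals.std(ddof=1))
            if len(vals) > 1 else 0.0, "max": float(vals.max())}
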