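"""Planar landmark contours and their square-root velocity representations.

A subject's anatomical contour (e.g. the corpus callosum outline on the
mid-sagittal slice) arrives as an ordered ``m x 2`` landmark matrix in
arbitrary image units.  Shape analysis requires removing the
shape-preserving transformations.  Translation and scale are removed by
arc-length normalization; the curve is then mapped to its square-root
velocity function (SRVF)

    q(s) = f'(s) / sqrt(|f'(s)|),

under which the elastic metric on curves becomes the flat L2 metric, and
rotation and reparameterization act as isometries (handled in
:mod:`shapemed.register`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkCurve",
    "CoordinateFunctions",
    "SRVFCurve",
    "normalize_landmarks",
    "srvf_transform",
    "srvf_inverse",
    "read_landmarks",
    "write_aligned_srvfs",
    "read_aligned_srvfs",
]

#: relative speed threshold below which the SRVF is set to zero
EPS_SPEED = 1e-12


@dataclass
class LandmarkCurve:
    """Ordered planar landmarks for one subject.

    Parameters
    ----------
    points
        ``m x 2`` array of contour coordinates, ordered along the contour.
    subject_id
        Identifier carried through the pipeline.
    """

    points: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError(
                f"landmarks must be an m x 2 matrix, got shape {self.points.shape}"
                f" (subject {self.subject_id!r})"
            )
        if self.points.shape[0] < 3:
            raise ValueError(
                f"need at least 3 landmarks, got {self.points.shape[0]}"
                f" (subject {self.subject_id!r})"
            )
        if not np.isfinite(self.points).all():
            raise ValueError(f"non-finite landmark coordinates (subject {self.subject_id!r})")
        seg = np.diff(self.points, axis=0)
        if np.hypot(seg[:, 0], seg[:, 1]).sum() == 0.0:
            raise ValueError(f"degenerate contour with zero arc length (subject {self.subject_id!r})")


@dataclass
class CoordinateFunctions:
    """Normalized coordinate functions f(s) = (f1(s), f2(s)) on a grid over [0, 1]."""

    grid: np.ndarray
    values: np.ndarray  # T x 2
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or self.values.shape != (self.grid.size, 2):
            raise ValueError("values must be T x 2 on a length-T grid")
        if self.grid[0] != 0.0 or self.grid[-1] != 1.0 or np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must increase strictly from 0 to 1")


@dataclass
class SRVFCurve:
    """Square-root velocity function on a grid over [0, 1].

    ``values[t]`` holds q(grid[t]) in units of sqrt(speed).  When derived
    from a unit-length curve with ``unit_norm=True`` the squared L2 norm
    integrates to one.
    """

    grid: np.ndarray
    values: np.ndarray  # T x 2
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or self.values.shape != (self.grid.size, 2):
            raise ValueError("values must be T x 2 on a length-T grid")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite SRVF values")

    def norm(self) -> float:
        """L2 norm sqrt(int |q(s)|^2 ds) by trapezoidal quadrature."""
        return float(np.sqrt(np.trapezoid((self.values**2).sum(axis=1), self.grid)))


def _arc_length_param(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Cumulative normalized arc length of a polyline and its total length."""
    seg = np.diff(points, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    total = float(seglen.sum())
    if total == 0.0:
        raise ValueError("degenerate contour with zero arc length")
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    return cum / total, total


def normalize_landmarks(curve: LandmarkCurve, n_grid: int) -> CoordinateFunctions:
    """Resample a contour by arc length and remove translation and scale.

    The polyline is resampled to ``n_grid`` points uniformly spaced in
    normalized arc length, centered at its centroid, and scaled to unit
    total arc length.  The output is therefore invariant to translating
    and uniformly scaling the input landmarks.
    """
    if n_grid < 3:
        raise ValueError(f"n_grid must be >= 3, got {n_grid}")
    pts = curve.points
    u, _ = _arc_length_param(pts)
    # collapse exactly repeated consecutive landmarks so interp is well defined
    keep = np.concatenate([[True], np.diff(u) > 0])
    u, pts = u[keep], pts[keep]
    grid = np.linspace(0.0, 1.0, n_grid)
    vals = np.column_stack([np.interp(grid, u, pts[:, 0]), np.interp(grid, u, pts[:, 1])])
    vals -= vals.mean(axis=0)
    _, total = _arc_length_param(vals)
    if total == 0.0:
        raise ValueError(f"zero arc length after resampling (subject {curve.subject_id!r})")
    vals /= total
    return CoordinateFunctions(grid=grid, values=vals, subject_id=curve.subject_id)


def srvf_transform(f: CoordinateFunctions, unit_norm: bool = False) -> SRVFCurve:
    """Map coordinate functions to their square-root velocity function.

    Derivatives are central finite differences on the uniform grid
    (one-sided at the endpoints).  Where the speed ``|f'(s)|`` falls below
    ``EPS_SPEED`` times the mean speed, q is set to zero.

    With ``unit_norm=True`` the result is rescaled to exact unit L2 norm;
    this pins down the discrete counterpart of the unit-arc-length
    convention, which finite differencing only achieves to O(h^2).
    """
    grid, vals = f.grid, f.values
    df = np.gradient(vals, grid, axis=0)
    speed = np.hypot(df[:, 0], df[:, 1])
    thresh = EPS_SPEED * speed.mean()
    safe = np.where(speed > thresh, speed, 1.0)
    q = df / np.sqrt(safe)[:, None]
    q[speed <= thresh] = 0.0
    out = SRVFCurve(grid=grid.copy(), values=q, subject_id=f.subject_id)
    if unit_norm:
        nrm = out.norm()
        if nrm == 0.0:
            raise ValueError("cannot normalize an identically zero SRVF")
        out.values = out.values / nrm
    return out


def srvf_inverse(q: SRVFCurve, start: tuple[float, float] = (0.0, 0.0)) -> CoordinateFunctions:
    """Reconstruct coordinate functions from an SRVF.

    Uses f(s) = start + int_0^s q(t) |q(t)| dt with cumulative trapezoidal
    integration; inverts :func:`srvf_transform` up to translation and grid
    error.
    """
    from scipy.integrate import cumulative_trapezoid

    mag = np.hypot(q.values[:, 0], q.values[:, 1])
    integrand = q.values * mag[:, None]
    f = cumulative_trapezoid(integrand, q.grid, axis=0, initial=0.0)
    f += np.asarray(start, dtype=float)
    # srvf_inverse output need not start/end at grid endpoints 0/1 in value,
    # only in parameter; grid is shared with q.
    return CoordinateFunctions(grid=q.grid.copy(), values=f, subject_id=q.subject_id)


# ---------------------------------------------------------------------------
# I/O


def read_landmarks(path) -> list[LandmarkCurve]:
    """Read contours from a long-format CSV/TSV.

    Expected columns: ``subject_id, point_index, x, y``; points are assumed
    ordered along the contour by ``point_index`` within each subject.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"subject_id", "point_index", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"landmark table must have columns {sorted(required)}")
    curves = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("point_index")
        curves.append(LandmarkCurve(points=grp[["x", "y"]].to_numpy(), subject_id=str(sid)))
    return curves


def write_aligned_srvfs(path, curves: list[SRVFCurve]) -> None:
    """Write aligned SRVFs to CSV with columns subject_id, s, q1, q2."""
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {"subject_id": c.subject_id, "s": c.grid, "q1": c.values[:, 0], "q2": c.values[:, 1]}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_aligned_srvfs(path) -> list[SRVFCurve]:
    """Inverse of :func:`write_aligned_srvfs`."""
    df = pd.read_csv(path)
    out = []
    for sid, grp in df.groupby("subject_id", sort=True):
        out.append(
            SRVFCurve(
                grid=grp["s"].to_numpy(),
                values=grp[["q1", "q2"]].to_numpy(),
                subject_id=str(sid),
            )
        )
    return out
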