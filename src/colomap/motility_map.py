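"""Spatiotemporal motility mapping of a cine image series.

The analysis follows the semi-automatic diameter-mapping approach used for
bowel cine-MRI: the user supplies a midline through the colon segment and a
corridor bracketing its walls; the software casts lines perpendicular to the
midline, measures the luminal diameter along each line in every frame, and
summarises motility as (a) frame-to-frame diameter change and (b) the
residuals of a per-position straight-line fit to the diameter time series —
the two-dimensional spatiotemporal residual map. Negative residuals mean
the lumen is narrower than its local trend, i.e. a contraction.

Geometry conventions: image coordinates in mm, origin at the centre of the
first pixel, ``x`` along columns, ``y`` along rows; arc-length origin at the
proximal (first) end of the midline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.colors import LinearSegmentedColormap
from scipy.spatial import cKDTree

from colomap._types import ImageSeries


@dataclass
class MidlineCurve:
    """User-drawn midline: ordered 2-D points in mm."""

    points_mm: np.ndarray

    def __post_init__(self) -> None:
        self.points_mm = np.asarray(self.points_mm, dtype=float)
        if self.points_mm.ndim != 2 or self.points_mm.shape[1] != 2:
            raise ValueError("midline points must be an (N, 2) array")
        if self.points_mm.shape[0] < 2:
            raise ValueError("midline needs at least 2 points")
        seg = np.linalg.norm(np.diff(self.points_mm, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("consecutive midline points must be distinct")
        self._arclengths = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def arclengths_mm(self) -> np.ndarray:
        return self._arclengths

    @property
    def total_length_mm(self) -> float:
        return float(self._arclengths[-1])

    def point_at(self, s: np.ndarray | float) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        x = np.interp(s, self._arclengths, self.points_mm[:, 0])
        y = np.interp(s, self._arclengths, self.points_mm[:, 1])
        return np.column_stack([x, y])


@dataclass
class WallCorridor:
    """Two open polylines bracketing the lumen, plus a search margin.

    The wall delineation is treated as a *search corridor*: edges are
    re-detected per frame within (distance to the corridor) + ``margin_mm``
    of the midline, which reconciles a one-off user delineation with
    frame-to-frame wall motion.
    """

    side_a_mm: np.ndarray
    side_b_mm: np.ndarray
    margin_mm: float = 10.0

    def __post_init__(self) -> None:
        self.side_a_mm = np.asarray(self.side_a_mm, dtype=float)
        self.side_b_mm = np.asarray(self.side_b_mm, dtype=float)
        for side in (self.side_a_mm, self.side_b_mm):
            if side.ndim != 2 or side.shape[1] != 2 or side.shape[0] < 2:
                raise ValueError("corridor sides must be (N>=2, 2) polylines")
        if self.margin_mm < 0:
            raise ValueError("margin_mm must be >= 0")


@dataclass
class MidlineSamples:
    """Regularly spaced midline samples with local frame vectors."""

    positions_mm: np.ndarray  # arc-lengths 0, ds, 2 ds, ...
    points_mm: np.ndarray  # (n, 2)
    tangents: np.ndarray  # (n, 2) unit
    normals: np.ndarray  # (n, 2) unit, tangent rotated +90 deg


@dataclass
class DiameterProfileSeries:
    """Measured lumen diameter d(s, t) with per-cell validity."""

    diameters_mm: np.ndarray  # (n_positions, n_frames)
    valid: np.ndarray  # bool, same shape
    positions_mm: np.ndarray
    times_s: np.ndarray

    def __post_init__(self) -> None:
        d, v = np.asarray(self.diameters_mm), np.asarray(self.valid, dtype=bool)
        if d.shape != v.shape:
            raise ValueError("diameters and validity mask must share a shape")
        if np.any(d[v] < 0):
            raise ValueError("valid diameters must be >= 0")


@dataclass
class ActivityMap:
    """First difference of the diameter series along time."""

    delta_mm: np.ndarray  # (n_positions, n_frames - 1)
    valid: np.ndarray
    positions_mm: np.ndarray
    times_s: np.ndarray  # left edge of each difference interval


@dataclass
class ResidualMap:
    """Per-position linearly detrended diameter series r(s, t)."""

    residuals_mm: np.ndarray
    valid: np.ndarray
    positions_mm: np.ndarray
    times_s: np.ndarray
    intercepts_mm: np.ndarray  # a_s, NaN where position masked
    slopes_mm_per_s: np.ndarray  # b_s


def resample_midline(curve: MidlineCurve, spacing_mm: float) -> MidlineSamples:
    """Sample the midline at arc-lengths 0, ds, 2 ds, ... with unit frames.

    Tangents use centred finite differences (one-sided at the endpoints);
    the normal is the tangent rotated +90 degrees.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing_mm must be > 0")
    total = curve.total_length_mm
    if spacing_mm > total:
        raise ValueError("spacing exceeds the midline arc length")
    n = int(np.floor(total / spacing_mm + 1e-9)) + 1
    s = np.arange(n) * spacing_mm
    pts = curve.point_at(s)
    tang = np.empty_like(pts)
    tang[1:-1] = pts[2:] - pts[:-2]
    tang[0] = pts[1] - pts[0]
    tang[-1] = pts[-1] - pts[-2]
    norms = np.linalg.norm(tang, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("degenerate midline: zero-length tangent")
    tang /= norms
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    return MidlineSamples(positions_mm=s, points_mm=pts, tangents=tang, normals=normal)


def _side_search_ranges(
    samples: MidlineSamples, corridor: WallCorridor
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample search range (mm) along +normal and -normal.

    Each corridor polyline is assigned to the normal side it lies on; the
    range on a side is the distance to that side's nearest corridor point
    plus the margin.
    """
    ranges = {}
    for name, poly in (("a", corridor.side_a_mm), ("b", corridor.side_b_mm)):
        tree = cKDTree(poly)
        dist, idx = tree.query(samples.points_mm)
        offs = poly[idx] - samples.points_mm
        sign_dots = np.einsum("ij,ij->i", offs, samples.normals)
        side = np.sign(np.median(np.sign(sign_dots)))
        if side == 0:
            raise ValueError("corridor polyline coincides with the midline")
        ranges[name] = (side, dist + corridor.margin_mm)
    (sa, ra), (sb, rb) = ranges["a"], ranges["b"]
    if sa == sb:
        raise ValueError("both corridor polylines lie on the same side of the midline")
    plus = ra if sa > 0 else rb
    minus = rb if sa > 0 else ra
    return plus, minus


def _bilinear_gather(
    frames: np.ndarray, rows: np.ndarray, cols: np.ndarray
) -> np.ndarray:
    """Sample frames (R, C, T) at fractional (rows, cols); NaN out of bounds.

    Returns an array of shape ``rows.shape + (T,)``.
    """
    R, C, _ = frames.shape
    inb = (rows >= 0) & (rows <= R - 1) & (cols >= 0) & (cols <= C - 1)
    r = np.clip(rows, 0, R - 1)
    c = np.clip(cols, 0, C - 1)
    r0 = np.clip(np.floor(r).astype(int), 0, R - 2)
    c0 = np.clip(np.floor(c).astype(int), 0, C - 2)
    fr = (r - r0)[..., None]
    fc = (c - c0)[..., None]
    out = (
        frames[r0, c0] * (1 - fr) * (1 - fc)
        + frames[r0 + 1, c0] * fr * (1 - fc)
        + frames[r0, c0 + 1] * (1 - fr) * fc
        + frames[r0 + 1, c0 + 1] * fr * fc
    )
    out[~inb] = np.nan
    return out


def _side_extents(
    profiles: np.ndarray, step_valid: np.ndarray, step_mm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Half-maximum edge distance along each ray.

    ``profiles``: (n_pos, n_steps, n_t); sample 0 is on the midline.
    ``step_valid``: (n_pos, n_steps) bool — in-bounds and inside the search
    corridor, already truncated at the first invalid step.

    The background level per ray is the median of its outermost valid
    samples; the wall is the first outward crossing of the half-maximum
    between the midline (lumen) intensity and that background, located with
    sub-step linear interpolation.
    """
    n_pos, n_steps, n_t = profiles.shape
    prof = np.where(step_valid[:, :, None], profiles, np.nan)
    lumen = prof[:, 0, :]  # (n_pos, n_t)

    n_valid = step_valid.sum(axis=1)
    extents = np.full((n_pos, n_t), np.nan)
    ok = np.zeros((n_pos, n_t), dtype=bool)
    for i in range(n_pos):
        nv = int(n_valid[i])
        if nv < 3:
            continue
        tail = max(3, nv // 4)
        bg = np.nanmedian(prof[i, nv - tail : nv, :], axis=0)  # (n_t,)
        thresh = bg + 0.5 * (lumen[i] - bg)
        seg = prof[i, :nv, :]  # (nv, n_t)
        below = seg < thresh[None, :]
        below[np.isnan(seg)] = False
        has = below.any(axis=0)
        j = np.argmax(below, axis=0)  # first crossing index per time
        good = has & (j > 0) & (lumen[i] > bg + 1e-12)
        if not good.any():
            continue
        jj = j[good]
        t_idx = np.flatnonzero(good)
        y1 = seg[jj - 1, t_idx]
        y2 = seg[jj, t_idx]
        th = thresh[t_idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(y1 != y2, (y1 - th) / (y1 - y2), 0.5)
        frac = np.clip(frac, 0.0, 1.0)
        extents[i, t_idx] = (jj - 1 + frac) * step_mm
        ok[i, t_idx] = True
    return extents, ok


def measure_diameters(
    frames: ImageSeries,
    curve: MidlineCurve,
    corridor: WallCorridor,
    spacing_mm: float = 2.0,
) -> DiameterProfileSeries:
    """Measure perpendicular lumen diameters along the midline, per frame.

    At every sampled midline position a line perpendicular to the midline is
    cast to both sides; intensity is sampled by bilinear interpolation at
    half-pixel steps within the wall corridor plus its margin. The lumen
    extent on each side is the distance to the half-maximum crossing between
    the local lumen intensity (at the midline) and the background estimated
    at the outer end of the line; the diameter is the sum of both extents.
    Cells where either side has no crossing (edge out of corridor, line out
    of the field of view, midline outside the lumen) are masked invalid —
    never recorded as zero.
    """
    samples = resample_midline(curve, spacing_mm)
    sp = frames.pixel_spacing_mm
    step = sp / 2.0
    plus_range, minus_range = _side_search_ranges(samples, corridor)

    data = np.asarray(frames.data, dtype=np.float32)
    extents = []
    valids = []
    for sign, rng_mm in ((+1.0, plus_range), (-1.0, minus_range)):
        n_steps = int(np.ceil(rng_mm.max() / step)) + 1
        offsets = np.arange(n_steps) * step  # (n_steps,)
        pts = (
            samples.points_mm[:, None, :]
            + sign * samples.normals[:, None, :] * offsets[None, :, None]
        )  # (n_pos, n_steps, 2)
        rows = pts[..., 1] / sp
        cols = pts[..., 0] / sp
        R, C, _ = data.shape
        inb = (rows >= 0) & (rows <= R - 1) & (cols >= 0) & (cols <= C - 1)
        within = offsets[None, :] <= rng_mm[:, None] + 1e-9
        step_ok = inb & within
        # truncate each ray at its first invalid step
        step_ok = np.cumprod(step_ok, axis=1).astype(bool)
        prof = _bilinear_gather(data, rows, cols)
        ext, ok = _side_extents(prof, step_ok, step)
        extents.append(ext)
        valids.append(ok)

    valid = valids[0] & valids[1]
    diam = np.where(valid, extents[0] + extents[1], np.nan)
    return DiameterProfileSeries(
        diameters_mm=diam,
        valid=valid,
        positions_mm=samples.positions_mm,
        times_s=frames.times_s,
    )


def frame_to_frame_activity(diams: DiameterProfileSeries) -> ActivityMap:
    """Diameter change between consecutive frames: dd(s,t) = d(s,t+1) - d(s,t).

    A difference touching an invalid cell is invalid.
    """
    d = diams.diameters_mm
    if d.shape[1] < 2:
        raise ValueError("activity needs at least 2 frames")
    delta = d[:, 1:] - d[:, :-1]
    valid = diams.valid[:, 1:] & diams.valid[:, :-1]
    delta = np.where(valid, delta, np.nan)
    return ActivityMap(
        delta_mm=delta,
        valid=valid,
        positions_mm=diams.positions_mm,
        times_s=diams.times_s[:-1],
    )


def residual_map(diams: DiameterProfileSeries, min_valid_frames: int = 3) -> ResidualMap:
    """Per-position ordinary least-squares linear detrend of d(s, t).

    For each position ``s`` with at least ``min_valid_frames`` valid cells,
    fit ``d(s, t) ~ a_s + b_s t`` over the valid cells and keep the
    residuals. Positions with fewer valid frames are masked entirely. By
    the least-squares normal equations the residuals at each position sum
    to zero and are orthogonal to time.
    """
    d = diams.diameters_mm
    t = diams.times_s
    n_pos = d.shape[0]
    res = np.full_like(d, np.nan, dtype=float)
    valid = np.zeros_like(diams.valid)
    a = np.full(n_pos, np.nan)
    b = np.full(n_pos, np.nan)
    for i in range(n_pos):
        m = diams.valid[i]
        if m.sum() < min_valid_frames:
            continue
        coef = np.polyfit(t[m], d[i, m], 1)
        fit = np.polyval(coef, t)
        res[i, m] = d[i, m] - fit[m]
        valid[i, m] = True
        b[i], a[i] = coef[0], coef[1]
    return ResidualMap(
        residuals_mm=res,
        valid=valid,
        positions_mm=diams.positions_mm,
        times_s=t,
        intercepts_mm=a,
        slopes_mm_per_s=b,
    )


#: contraction-centric diverging map: deep troughs red, moderate yellow,
#: no change blue (dilation fades into dark blue)
MOTILITY_CMAP = LinearSegmentedColormap.from_list(
    "colomap_motility",
    [
        (0.00, "#d7191c"),  # strongly negative residual: contraction
        (0.28, "#ffd700"),  # intermediate negative: minimal activity
        (0.50, "#2c7bb6"),  # near zero: no change in diameter
        (1.00, "#10304f"),  # positive residual: dilation
    ],
)


def render_motility_plot(
    rmap: ResidualMap,
    out_path,
    limit_quantile: float = 0.99,
    dpi: int = 120,
) -> None:
    """Write the spatiotemporal motility plot as a PNG.

    Time (minutes) runs along the x-axis, arc-length position (mm) along the
    y-axis with the proximal end on top. Colour limits are symmetric at the
    given quantile of |r|; invalid cells are drawn light grey. Rendering is
    deterministic for identical maps.
    """
    r = np.ma.masked_array(rmap.residuals_mm, mask=~rmap.valid)
    finite = np.abs(rmap.residuals_mm[rmap.valid])
    lim = float(np.quantile(finite, limit_quantile)) if finite.size else 0.0
    if lim <= 0:
        lim = 1e-6
    cmap = MOTILITY_CMAP.copy()
    cmap.set_bad("#d9d9d9")
    t_min = rmap.times_s / 60.0
    fig, ax = plt.subplots(figsize=(8, 4))
    dt = (t_min[1] - t_min[0]) if t_min.size > 1 else 1.0 / 60.0
    ds = (
        rmap.positions_mm[1] - rmap.positions_mm[0]
        if rmap.positions_mm.size > 1
        else 1.0
    )
    im = ax.imshow(
        r,
        aspect="auto",
        origin="upper",
        cmap=cmap,
        vmin=-lim,
        vmax=lim,
        extent=(
            t_min[0] - dt / 2,
            t_min[-1] + dt / 2,
            rmap.positions_mm[-1] + ds / 2,
            rmap.positions_mm[0] - ds / 2,
        ),
        interpolation="nearest",
    )
    ax.invert_yaxis()
    ax.set_xlabel("time (min)")
    ax.set_ylabel("position along midline (mm)")
    cbar = fig.colorbar(im, ax=ax)
    cbar.set_label("diameter residual (mm)")
    fig.savefig(out_path, dpi=dpi, metadata={"Software": "colomap"})
    plt.close(fig)


def estimate_ridge_velocity(
    rmap: ResidualMap,
    t_start_s: float | None = None,
    t_end_s: float | None = None,
    depth_fraction: float = 0.8,
) -> float:
    """Propagation velocity of a contraction band from the residual map.

    Within ``[t_start, t_end)`` the trough position ``argmin_s r(s, t)`` is
    tracked over the frames whose trough depth reaches ``depth_fraction`` of
    the window maximum (where the band is fully developed), and its slope
    versus time — the propagation velocity in mm/s — is fitted by ordinary
    least squares. Intended for windows containing a single band.
    """
    t = rmap.times_s
    sel = np.ones_like(t, dtype=bool)
    if t_start_s is not None:
        sel &= t >= t_start_s
    if t_end_s is not None:
        sel &= t < t_end_s
    r = np.where(rmap.valid, rmap.residuals_mm, np.inf)[:, sel]
    tt = t[sel]
    depth = -r.min(axis=0)
    depth[~np.isfinite(depth)] = -np.inf
    max_depth = depth.max()
    if not np.isfinite(max_depth) or max_depth <= 0:
        raise ValueError("no contraction band in the requested window")
    use = depth >= depth_fraction * max_depth
    if use.sum() < 3:
        raise ValueError("too few frames with a developed trough to fit a velocity")
    ridge_pos = rmap.positions_mm[np.argmin(r[:, use], axis=0)]
    return float(np.polyfit(tt[use], ridge_pos, 1)[0])
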