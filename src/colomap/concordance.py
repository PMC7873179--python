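"""Cross-modality agreement between manometric HAPCs and the motility map.

The two modalities are aligned on a common clock via a user-supplied offset
(manometry time minus image time); only the manometry channels lying inside
the imaged midline segment take part. Each HAPC window is then scored on
the residual map — the score is the deepest contraction trough (peak
negative residual) near the included channels during the window — and
labelled ``high`` / ``minimal`` / ``absent`` against two depth thresholds.
Activity episodes seen only on imaging are detected symmetrically.

The high/minimal thresholds are phantom-calibrated defaults (trough depth in
mm of a clear vs a marginal contraction on the synthetic data); they are
mandatory, explicit parameters for real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from colomap.manometry import HAPCEvent
from colomap.motility_map import ResidualMap

#: residual trough depth (mm) at/above which imaged activity is called high
THETA_HIGH_MM = 4.0
#: residual trough depth (mm) at/above which imaged activity is called minimal
THETA_MIN_MM = 1.0

LABELS = ("high", "minimal", "absent", "not_recorded")


@dataclass
class AlignedSession:
    """One simultaneous recording session on a common clock.

    ``clock_offset_s`` converts image time to manometry time:
    ``t_manometry = t_image + clock_offset_s``.
    ``channel_positions_mm`` maps catheter channel index to arc-length along
    the imaged midline; ``imaged_segment_mm`` is the half-open arc-length
    interval covered by the image.
    """

    rmap: ResidualMap
    hapcs: list[HAPCEvent]
    clock_offset_s: float
    channel_positions_mm: np.ndarray
    imaged_segment_mm: tuple[float, float]
    channel_spacing_mm: float = 100.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.clock_offset_s):
            raise ValueError("clock offset must be finite")
        self.channel_positions_mm = np.asarray(self.channel_positions_mm, dtype=float)
        lo, hi = self.imaged_segment_mm
        if not lo < hi:
            raise ValueError("imaged segment must be a non-empty [start, end) interval")

    @property
    def included_channels(self) -> np.ndarray:
        return map_channels_to_segment(self.channel_positions_mm, self.imaged_segment_mm)


@dataclass
class ActivityClassification:
    """Image-activity call for one HAPC window."""

    label: str  # one of LABELS
    score_mm: float  # peak negative-residual depth; NaN when not recorded
    window_s: tuple[float, float]  # image-clock window actually scored
    hapc: HAPCEvent | None = None


@dataclass
class Episode:
    """A maximal image-only activity interval (image clock, [start, end))."""

    start_s: float
    end_s: float
    peak_depth_mm: float
    label: str  # high or minimal
    overlaps_hapc: bool


@dataclass
class ConcordanceSummary:
    """Per-label counts and integer percentages over the HAPC list.

    ``percentages`` are rounded half up, computed per label over the total
    HAPC count (None when there are no HAPCs). ``merged`` folds
    ``not_recorded`` into ``absent`` for comparison with reports that do not
    keep the distinction.
    """

    counts: dict[str, int]
    percentages: dict[str, int | None]
    merged_counts: dict[str, int]
    merged_percentages: dict[str, int | None]
    n_hapcs: int
    mri_only_episodes: int
    session_id: str | None = None


def round_half_up(x: float) -> int:
    """Round a non-negative value half up to an integer (2/11 -> 18 %)."""
    return int(math.floor(x + 0.5))


def map_channels_to_segment(
    channel_positions_mm: np.ndarray, imaged_segment_mm: tuple[float, float]
) -> np.ndarray:
    """Indices of channels whose position lies in the half-open segment.

    Only channels visible on the image take part in any comparison; an
    empty result is a hard error because no cross-modality statement can be
    made without at least one shared channel.
    """
    pos = np.asarray(channel_positions_mm, dtype=float)
    lo, hi = imaged_segment_mm
    idx = np.flatnonzero((pos >= lo) & (pos < hi))
    if idx.size == 0:
        raise ValueError(
            "no manometry channel lies inside the imaged segment; "
            "cross-modality comparison is impossible"
        )
    return idx


def _window_depth(
    rmap: ResidualMap,
    positions_mask: np.ndarray,
    t_start_s: float,
    t_end_s: float,
) -> float | None:
    """Deepest trough (max of -r) over a position band and time window.

    Returns None when the window contains no frame of the map.
    """
    t = rmap.times_s
    t_sel = (t >= t_start_s) & (t < t_end_s)
    if not t_sel.any():
        return None
    sub = rmap.residuals_mm[np.ix_(positions_mask, t_sel)]
    sub_valid = rmap.valid[np.ix_(positions_mask, t_sel)]
    if not sub_valid.any():
        return 0.0
    return float(np.max(-sub[sub_valid]))


def classify_mri_activity(
    session: AlignedSession,
    hapc: HAPCEvent,
    theta_high_mm: float = THETA_HIGH_MM,
    theta_min_mm: float = THETA_MIN_MM,
    pad_s: float = 15.0,
) -> ActivityClassification:
    """Label the imaged activity during one HAPC window.

    The HAPC window (manometry clock) is shifted onto the image clock and
    padded by ``pad_s`` on both sides to absorb alignment uncertainty. The
    score is the peak negative residual over positions within half a channel
    spacing of any included channel, counting valid cells only. Windows
    falling entirely outside the imaging acquisition are labelled
    ``not_recorded`` — kept distinct from ``absent`` (imaged, no signal).
    """
    if not theta_high_mm > theta_min_mm > 0:
        raise ValueError("thresholds must satisfy theta_high > theta_min > 0")
    t0 = hapc.window_s[0] - session.clock_offset_s - pad_s
    t1 = hapc.window_s[1] - session.clock_offset_s + pad_s
    half = session.channel_spacing_mm / 2.0
    pos = session.rmap.positions_mm
    included = session.channel_positions_mm[session.included_channels]
    band = np.zeros(pos.size, dtype=bool)
    for p in included:
        band |= (pos >= p - half) & (pos < p + half)
    depth = _window_depth(session.rmap, band, t0, t1)
    if depth is None:
        return ActivityClassification(
            label="not_recorded", score_mm=math.nan, window_s=(t0, t1), hapc=hapc
        )
    if depth >= theta_high_mm:
        label = "high"
    elif depth >= theta_min_mm:
        label = "minimal"
    else:
        label = "absent"
    return ActivityClassification(label=label, score_mm=depth, window_s=(t0, t1), hapc=hapc)


def detect_mri_episodes(
    session: AlignedSession,
    theta_min_mm: float = THETA_MIN_MM,
    theta_high_mm: float = THETA_HIGH_MM,
    min_duration_s: float = 5.0,
    pad_s: float = 15.0,
) -> list[Episode]:
    """Find maximal image-activity intervals and flag HAPC overlap.

    An episode is a maximal run of frames where the deepest valid trough
    across positions reaches ``theta_min_mm``, lasting at least
    ``min_duration_s``; it is labelled high when its peak depth reaches
    ``theta_high_mm``. Overlap is checked against the HAPC windows shifted
    to the image clock and padded by ``pad_s``.
    """
    rmap = session.rmap
    t = rmap.times_s
    depth = np.where(rmap.valid, -rmap.residuals_mm, -np.inf).max(axis=0)
    active = depth >= theta_min_mm
    if t.size > 1:
        dt = t[1] - t[0]
    else:
        dt = min_duration_s
    episodes: list[Episode] = []
    edges = np.diff(active.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if active.size and active[0]:
        starts.insert(0, 0)
    if active.size and active[-1]:
        ends.append(active.size)
    hapc_windows = [
        (h.window_s[0] - session.clock_offset_s - pad_s,
         h.window_s[1] - session.clock_offset_s + pad_s)
        for h in session.hapcs
    ]
    for i0, i1 in zip(starts, ends):
        start_s, end_s = t[i0], t[i1 - 1] + dt
        if end_s - start_s < min_duration_s:
            continue
        peak = float(depth[i0:i1].max())
        overlaps = any(start_s < w1 and w0 < end_s for w0, w1 in hapc_windows)
        episodes.append(
            Episode(
                start_s=float(start_s),
                end_s=float(end_s),
                peak_depth_mm=peak,
                label="high" if peak >= theta_high_mm else "minimal",
                overlaps_hapc=overlaps,
            )
        )
    episodes.sort(key=lambda e: e.start_s)
    return episodes


def concordance_summary(
    classifications: list[ActivityClassification],
    episodes: list[Episode] | None = None,
    session_id: str | None = None,
) -> ConcordanceSummary:
    """Tally per-HAPC labels into counts and integer percentages.

    Percentages are round-half-up integers of ``100 * count / total`` and
    None when there are no HAPCs. The merged view folds ``not_recorded``
    into ``absent``. The count of image-only episodes (no HAPC overlap) is
    carried alongside.
    """
    counts = {label: 0 for label in LABELS}
    for c in classifications:
        if c.label not in counts:
            raise ValueError(f"unknown label {c.label!r}")
        counts[c.label] += 1
    total = sum(counts.values())
    if total:
        percentages = {k: round_half_up(100.0 * v / total) for k, v in counts.items()}
    else:
        percentages = {k: None for k in counts}
    merged = {
        "high": counts["high"],
        "minimal": counts["minimal"],
        "absent": counts["absent"] + counts["not_recorded"],
    }
    if total:
        merged_pct = {k: round_half_up(100.0 * v / total) for k, v in merged.items()}
    else:
        merged_pct = {k: None for k in merged}
    mri_only = sum(1 for e in (episodes or []) if not e.overlaps_hapc)
    return ConcordanceSummary(
        counts=counts,
        percentages=percentages,
        merged_counts=merged,
        merged_percentages=merged_pct,
        n_hapcs=total,
        mri_only_episodes=mri_only,
        session_id=session_id,
    )


def summarise_patient_counts(hapc_counts_per_patient: list[int]) -> dict[str, int]:
    """Aggregate per-patient HAPC counts: total and patients with >= 1."""
    counts = [int(c) for c in hapc_counts_per_patient]
    if any(c < 0 for c in counts):
        raise ValueError("HAPC counts must be non-negative")
    return {
        "total_hapcs": sum(counts),
        "patients_with_hapcs": sum(1 for c in counts if c >= 1),
        "n_patients": len(counts),
    }


def render_overlay(
    session: AlignedSession,
    out_path,
    limit_quantile: float = 0.99,
    pad_s: float = 15.0,
    dpi: int = 120,
) -> None:
    """Residual map with HAPC windows as vertical bands and channel ticks."""
    import matplotlib.pyplot as plt

    from colomap.motility_map import MOTILITY_CMAP

    rmap = session.rmap
    r = np.ma.masked_array(rmap.residuals_mm, mask=~rmap.valid)
    finite = np.abs(rmap.residuals_mm[rmap.valid])
    lim = float(np.quantile(finite, limit_quantile)) if finite.size else 1e-6
    lim = max(lim, 1e-6)
    cmap = MOTILITY_CMAP.copy()
    cmap.set_bad("#d9d9d9")
    t_min = rmap.times_s / 60.0
    fig, ax = plt.subplots(figsize=(9, 4))
    im = ax.imshow(
        r,
        aspect="auto",
        origin="upper",
        cmap=cmap,
        vmin=-lim,
        vmax=lim,
        extent=(t_min[0], t_min[-1], rmap.positions_mm[-1], rmap.positions_mm[0]),
        interpolation="nearest",
    )
    ax.invert_yaxis()
    for h in session.hapcs:
        w0 = (h.window_s[0] - session.clock_offset_s - pad_s) / 60.0
        w1 = (h.window_s[1] - session.clock_offset_s + pad_s) / 60.0
        ax.axvspan(w0, w1, color="k", alpha=0.15, lw=0)
    for p in session.channel_positions_mm[session.included_channels]:
        ax.axhline(p, color="w", ls=":", lw=0.8)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("position along midline (mm)")
    fig.colorbar(im, ax=ax, label="diameter residual (mm)")
    fig.savefig(out_path, dpi=dpi, metadata={"Software": "colomap"})
    plt.close(fig)
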