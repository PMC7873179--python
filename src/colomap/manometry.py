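"""Contraction-event detection and HAPC classification from pressure traces.

High-amplitude propagating contractions (HAPCs) are the colonic motor
pattern of interest: clusters of contractions with peak amplitude of at
least 60 mmHg above baseline, propagating antegradely (proximal to distal)
across at least three adjacent recording sites. Water-perfused catheters
drift, so per-channel baselines are tracked with a rolling median before
thresholding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

#: per-site peak amplitude (above baseline) an HAPC contraction must reach, mmHg
HAPC_AMPLITUDE_MMHG = 60.0
#: minimum number of adjacent recording sites an HAPC must traverse
HAPC_MIN_SITES = 3


@dataclass
class PressureRecording:
    """Multi-channel manometry traces with sensor geometry.

    ``pressures_mmhg`` has shape ``(n_channels, n_samples)``; channels are
    ordered proximal to distal (increasing arc-length). Default catheter
    geometry spaces recording sites 100 mm apart.
    """

    pressures_mmhg: np.ndarray
    sampling_rate_hz: float
    channel_positions_mm: np.ndarray
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pressures_mmhg = np.atleast_2d(np.asarray(self.pressures_mmhg, dtype=float))
        self.channel_positions_mm = np.asarray(self.channel_positions_mm, dtype=float)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if self.channel_positions_mm.size != self.pressures_mmhg.shape[0]:
            raise ValueError(
                f"{self.pressures_mmhg.shape[0]} channels but "
                f"{self.channel_positions_mm.size} positions"
            )
        if np.any(np.diff(self.channel_positions_mm) <= 0):
            raise ValueError("channel positions must be strictly increasing (proximal->distal)")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i + 1}" for i in range(self.n_channels)]

    @property
    def n_channels(self) -> int:
        return self.pressures_mmhg.shape[0]

    @property
    def n_samples(self) -> int:
        return self.pressures_mmhg.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass
class ContractionEvent:
    """A single-channel pressure event above baseline."""

    channel: int
    onset_s: float
    peak_s: float
    amplitude_mmhg: float  # peak excess over rolling baseline
    end_s: float

    def __post_init__(self) -> None:
        if not self.onset_s <= self.peak_s <= self.end_s:
            raise ValueError("event requires onset <= peak <= end")
        if self.amplitude_mmhg <= 0:
            raise ValueError("amplitude must be > 0")


@dataclass
class HAPCEvent:
    """A chain of contractions propagating antegradely across >= 3 sites."""

    channels: list[int]  # contiguous, increasing
    onsets_s: list[float]  # strictly increasing with position
    amplitudes_mmhg: list[float]
    min_amplitude_mmhg: float
    velocity_mm_s: float  # NaN when undefined
    velocity_defined: bool
    window_s: tuple[float, float]  # [start, end)

    @property
    def span(self) -> int:
        return len(self.channels)


def _rolling_baseline(trace: np.ndarray, window_samples: int) -> np.ndarray:
    """Centred rolling median; resists contamination by contraction peaks."""
    size = max(3, int(window_samples) | 1)  # odd
    return ndimage.median_filter(trace, size=size, mode="nearest")


def detect_contractions(
    rec: PressureRecording,
    min_amplitude_mmhg: float = 20.0,
    baseline_window_s: float = 120.0,
) -> list[ContractionEvent]:
    """Detect per-channel contraction events by baseline-excess thresholding.

    Per channel, the baseline is a centred rolling median over
    ``baseline_window_s``. Candidate events are maximal intervals where the
    excess pressure exceeds ``min_amplitude / 2``; an event is retained if
    its peak excess reaches ``min_amplitude``. The onset is placed at the
    last upward crossing of 20 % of the peak excess before the peak, and
    the end at the first downward crossing of 20 % after it.

    Events are returned sorted by onset time, then channel.
    """
    if rec.duration_s < 2.0 * baseline_window_s:
        raise ValueError(
            f"recording ({rec.duration_s:.0f} s) must be at least twice the "
            f"baseline window ({baseline_window_s:.0f} s)"
        )
    if not np.all(np.isfinite(rec.pressures_mmhg)):
        ch, samp = np.argwhere(~np.isfinite(rec.pressures_mmhg))[0]
        raise ValueError(f"non-finite pressure sample at channel {ch}, sample {samp}")

    dt = 1.0 / rec.sampling_rate_hz
    window_samples = int(round(baseline_window_s * rec.sampling_rate_hz))
    events: list[ContractionEvent] = []
    for ch in range(rec.n_channels):
        trace = rec.pressures_mmhg[ch]
        excess = trace - _rolling_baseline(trace, window_samples)
        above = excess > min_amplitude_mmhg / 2.0
        if not above.any():
            continue
        edges = np.diff(above.astype(int))
        starts = list(np.flatnonzero(edges == 1) + 1)
        ends = list(np.flatnonzero(edges == -1) + 1)  # exclusive
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            ends.append(above.size)
        for i0, i1 in zip(starts, ends):
            seg = excess[i0:i1]
            peak_rel = int(np.argmax(seg))
            peak_exc = float(seg[peak_rel])
            if peak_exc < min_amplitude_mmhg:
                continue
            peak_idx = i0 + peak_rel
            thresh = 0.2 * peak_exc
            onset_idx = i0
            below = np.flatnonzero(excess[i0 : peak_idx + 1] < thresh)
            if below.size:
                onset_idx = i0 + below[-1] + 1
            end_idx = i1 - 1
            below_after = np.flatnonzero(excess[peak_idx:i1] < thresh)
            if below_after.size:
                end_idx = peak_idx + below_after[0]
            events.append(
                ContractionEvent(
                    channel=ch,
                    onset_s=onset_idx * dt,
                    peak_s=peak_idx * dt,
                    amplitude_mmhg=peak_exc,
                    end_s=end_idx * dt,
                )
            )
    events.sort(key=lambda e: (e.onset_s, e.channel))
    return events


def detect_hapcs(
    events: list[ContractionEvent],
    rec: PressureRecording,
    amp_threshold_mmhg: float = HAPC_AMPLITUDE_MMHG,
    max_lag_s: float = 60.0,
    max_velocity_mm_s: float = 50.0,
    amplitude_mode: str = "per_site",
) -> list[HAPCEvent]:
    """Chain contraction events into HAPCs.

    Starting from each unused event in onset order, the chain is extended
    distally: the next member is the earliest unused event on the adjacent
    distal channel whose onset is strictly later by at most ``max_lag_s``
    and whose implied velocity does not exceed ``max_velocity_mm_s``. A
    chain qualifies as an HAPC iff it spans at least three adjacent
    channels and meets the amplitude criterion — by default every
    participating contraction must reach ``amp_threshold_mmhg``
    (``amplitude_mode="per_site"``); ``"mean"`` requires the chain mean
    instead. Events join at most one HAPC.
    """
    if amplitude_mode not in ("per_site", "mean"):
        raise ValueError("amplitude_mode must be 'per_site' or 'mean'")
    positions = rec.channel_positions_mm
    ordered = sorted(events, key=lambda e: (e.onset_s, e.channel))
    used: set[int] = set()
    by_channel: dict[int, list[int]] = {}
    for i, ev in enumerate(ordered):
        by_channel.setdefault(ev.channel, []).append(i)

    hapcs: list[HAPCEvent] = []
    for start in range(len(ordered)):
        if start in used:
            continue
        chain = [start]
        while True:
            cur = ordered[chain[-1]]
            nxt_ch = cur.channel + 1
            candidate = None
            for j in by_channel.get(nxt_ch, []):
                if j in used or j in chain:
                    continue
                ev = ordered[j]
                dt = ev.onset_s - cur.onset_s
                if dt <= 0 or dt > max_lag_s:
                    continue
                dx = positions[nxt_ch] - positions[cur.channel]
                if dx / dt > max_velocity_mm_s:
                    continue
                candidate = j
                break  # events per channel are onset-ordered: earliest admissible
            if candidate is None:
                break
            chain.append(candidate)
        if len(chain) < HAPC_MIN_SITES:
            continue
        amps = [ordered[j].amplitude_mmhg for j in chain]
        if amplitude_mode == "per_site":
            ok = min(amps) >= amp_threshold_mmhg
        else:
            ok = float(np.mean(amps)) >= amp_threshold_mmhg
        if not ok:
            continue
        used.update(chain)
        chans = [ordered[j].channel for j in chain]
        onsets = [ordered[j].onset_s for j in chain]
        vel, defined = _fit_velocity(positions[chans], np.asarray(onsets))
        hapcs.append(
            HAPCEvent(
                channels=chans,
                onsets_s=onsets,
                amplitudes_mmhg=amps,
                min_amplitude_mmhg=float(min(amps)),
                velocity_mm_s=vel,
                velocity_defined=defined,
                window_s=(onsets[0], max(ordered[j].end_s for j in chain)),
            )
        )
    hapcs.sort(key=lambda h: h.window_s[0])
    return hapcs


def _fit_velocity(positions: np.ndarray, onsets: np.ndarray) -> tuple[float, bool]:
    if np.ptp(onsets) == 0:
        return math.nan, False
    slope = np.polyfit(onsets, positions, 1)[0]
    return float(slope), True


def estimate_velocity(hapc: HAPCEvent, positions_mm: np.ndarray | None = None) -> float:
    """Propagation velocity as the least-squares slope of position vs onset.

    Positive = antegrade. ``positions_mm`` are the full catheter channel
    positions; when omitted the velocity stored on the event (fitted at
    detection time) is returned. A zero onset spread leaves the velocity
    undefined: NaN is returned and ``hapc.velocity_defined`` is False.
    """
    if hapc.span < HAPC_MIN_SITES:
        raise ValueError("velocity estimation requires >= 3 participating channels")
    if positions_mm is None:
        return hapc.velocity_mm_s
    pos = np.asarray(positions_mm, dtype=float)[hapc.channels]
    vel, defined = _fit_velocity(pos, np.asarray(hapc.onsets_s))
    hapc.velocity_mm_s = vel
    hapc.velocity_defined = defined
    return vel
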