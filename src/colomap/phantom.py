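"""Coupled peristalsis phantom: cine image series + manometry traces.

A single ground-truth lumen-diameter field ``D(s, t)`` (arc-length position
``s`` along the colon midline, time ``t``) drives both simulated modalities:

* image frames show a bright-lumen tube of local full width ``D(s, t)``
  centred on the midline, with optional breathing displacement and noise;
* intraluminal pressure at a sensor rises as the lumen at that position
  occludes, emulating a water-perfused catheter whose ports are blocked by
  the contracting wall.

Contraction waves are Gaussian troughs in arc-length translating at constant
velocity (positive velocity = antegrade, towards increasing arc-length).
The multiplicative wave model keeps the ground truth in closed form:

``D(s,t) = clamp(D0 * prod_k [1 - A_k exp(-(s - s0_k - v_k (t-t0_k))^2 /
(2 sigma_k^2)) * active_k(t)], floor, D0)``
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from colomap._types import ImageSeries
from colomap.manometry import PressureRecording


@dataclass
class WaveSpec:
    """One propagating contraction wave (HAPC-like).

    Parameters
    ----------
    onset_time_s
        Time at which the wave appears at its origin.
    origin_mm
        Arc-length position of the trough centre at onset.
    velocity_mm_s
        Propagation velocity; positive = antegrade (proximal to distal).
    amplitude_fraction
        Fractional occlusion at the trough centre, in [0, 1]; 1 means the
        lumen closes down to the occlusion floor.
    half_width_mm
        Gaussian sigma of the trough in arc-length.
    tail_length_mm
        Arc-length extent the wave traverses before dying out; ``None``
        (default) lets the wave run indefinitely.
    """

    onset_time_s: float
    origin_mm: float
    velocity_mm_s: float
    amplitude_fraction: float
    half_width_mm: float
    tail_length_mm: float | None = None

    def __post_init__(self) -> None:
        if self.velocity_mm_s == 0:
            raise ValueError("propagating wave requires velocity != 0")
        if self.half_width_mm <= 0:
            raise ValueError("half_width_mm must be > 0")
        if not 0.0 <= self.amplitude_fraction <= 1.0:
            raise ValueError("amplitude_fraction must be in [0, 1]")
        if self.tail_length_mm is not None and self.tail_length_mm <= 0:
            raise ValueError("tail_length_mm must be > 0 when given")

    @property
    def end_time_s(self) -> float:
        """Time the wave dies out (inf when untruncated)."""
        if self.tail_length_mm is None:
            return np.inf
        return self.onset_time_s + self.tail_length_mm / abs(self.velocity_mm_s)

    def trough_centre_mm(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.origin_mm + self.velocity_mm_s * (np.asarray(t) - self.onset_time_s)


@dataclass
class BackgroundActivity:
    """Low-amplitude, non-propagating contraction events.

    Events are drawn from the seeded generator at ``rate_per_min`` with
    uniformly random positions and start times; each is a Gaussian trough in
    arc-length (sigma = ``width_mm``) with a Hann temporal envelope of the
    given duration, superposed multiplicatively like the HAPC waves.
    """

    rate_per_min: float = 0.0
    amplitude_fraction: float = 0.15
    width_mm: float = 15.0
    duration_s: float = 8.0

    def __post_init__(self) -> None:
        if self.rate_per_min < 0:
            raise ValueError("rate_per_min must be >= 0")
        if not 0.0 <= self.amplitude_fraction <= 1.0:
            raise ValueError("amplitude_fraction must be in [0, 1]")
        if self.width_mm <= 0 or self.duration_s <= 0:
            raise ValueError("width_mm and duration_s must be > 0")


@dataclass
class Breathing:
    """Whole-frame rigid vertical sinusoidal displacement."""

    amplitude_mm: float = 0.0
    period_s: float = 4.0

    def __post_init__(self) -> None:
        if self.amplitude_mm < 0:
            raise ValueError("amplitude_mm must be >= 0")
        if self.period_s <= 0:
            raise ValueError("period_s must be > 0")


def _default_midline() -> list[tuple[float, float]]:
    return [(25.0, 60.0), (425.0, 60.0)]


def _default_sensors() -> list[float]:
    return [50.0, 150.0, 250.0, 350.0]


@dataclass
class PhantomConfig:
    """Full description of one phantom session.

    Defaults emulate the clinical acquisition this phantom stands in for:
    ~30 min of cine imaging at 1 frame/s of a descending-colon segment, a
    water-perfused catheter with recording sites every 10 cm (four of them
    inside the imaged segment), a ~20 mm baseline lumen and contraction
    waves that occlude most of it.
    """

    duration_s: float = 1800.0
    frame_interval_s: float = 1.0
    pixel_spacing_mm: float = 1.5
    image_shape: tuple[int, int] = (80, 300)  # (rows, cols)
    midline_control_points_mm: list[tuple[float, float]] = field(default_factory=_default_midline)
    baseline_diameter_mm: float = 20.0
    hapc_events: list[WaveSpec] = field(default_factory=list)
    background_activity: BackgroundActivity = field(default_factory=BackgroundActivity)
    breathing: Breathing = field(default_factory=Breathing)
    noise_sd: float = 0.0
    occlusion_floor_mm: float = 1.0
    sensor_positions_mm: list[float] = field(default_factory=_default_sensors)
    sensor_spacing_mm: float = 100.0
    pressure_baseline_mmhg: float = 10.0
    pressure_gain_mmhg: float = 100.0
    pressure_gamma: float = 1.0
    field_spacing_mm: float = 2.0
    lumen_intensity: float = 1.0
    background_intensity: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be > 0")
        if self.occlusion_floor_mm < 0:
            raise ValueError("occlusion_floor_mm must be >= 0")
        if self.baseline_diameter_mm <= self.occlusion_floor_mm:
            raise ValueError("baseline_diameter_mm must exceed occlusion_floor_mm")
        if self.field_spacing_mm <= 0:
            raise ValueError("field_spacing_mm must be > 0")
        pts = np.asarray(self.midline_control_points_mm, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
            raise ValueError("midline needs >= 2 two-dimensional control points")
        if np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
            raise ValueError("consecutive midline points must be distinct")
        sens = np.asarray(self.sensor_positions_mm, dtype=float)
        if sens.size and np.any(np.diff(sens) <= 0):
            raise ValueError("sensor positions must be strictly increasing")
        arc = self.midline_arclength_mm
        if sens.size and (sens[0] < 0 or sens[-1] > arc):
            raise ValueError(
                f"sensor positions must lie within the midline arc-length range [0, {arc:.1f}] mm"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def midline_points_mm(self) -> np.ndarray:
        return np.asarray(self.midline_control_points_mm, dtype=float)

    @property
    def midline_arclength_mm(self) -> float:
        pts = self.midline_points_mm
        return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))

    @property
    def times_s(self) -> np.ndarray:
        n = int(np.floor(self.duration_s / self.frame_interval_s))
        return np.arange(n) * self.frame_interval_s

    @property
    def positions_mm(self) -> np.ndarray:
        n = int(np.floor(self.midline_arclength_mm / self.field_spacing_mm)) + 1
        return np.arange(n) * self.field_spacing_mm

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic generator for one noise source."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


def wall_corridor(config: "PhantomConfig", offset_mm: float | None = None,
                  margin_mm: float = 10.0):
    """Wall-corridor polylines bracketing the phantom's relaxed lumen.

    Emulates the user's wall delineation: each side runs parallel to the
    midline at ``offset_mm`` (default: baseline radius + 3 mm).
    """
    from colomap.motility_map import MidlineCurve, WallCorridor, resample_midline

    if offset_mm is None:
        offset_mm = config.baseline_diameter_mm / 2.0 + 3.0
    fine = resample_midline(MidlineCurve(points_mm=config.midline_points_mm), 2.0)
    return WallCorridor(
        side_a_mm=fine.points_mm + offset_mm * fine.normals,
        side_b_mm=fine.points_mm - offset_mm * fine.normals,
        margin_mm=margin_mm,
    )


def reference_session_config(
    seed: int = 0,
    noise_sd: float = 0.0,
    pressure_noise_sd_mmhg: float = 0.0,
    breathing_amplitude_mm: float = 0.0,
) -> tuple["PhantomConfig", float]:
    """The package's reference validation scenario.

    A ~30 min session at 1 frame/s with three antegrade waves whose coupled
    pressure peaks all exceed the 60 mmHg HAPC criterion, traversing all
    four in-segment sensors. Returns the config and the pressure noise sd
    (the config itself is noise-free on the pressure side; the caller passes
    the sd to :func:`simulate_manometry`).

    Velocities (10, 8, 12 mm/s) and occlusion fractions (0.8, 0.7, 0.9) are
    within the physiological range of stimulant-induced propagating
    contractions; onsets are spaced far apart so each wave is an isolated
    event.
    """
    cfg = PhantomConfig(
        duration_s=1800.0,
        hapc_events=[
            WaveSpec(onset_time_s=300.0, origin_mm=0.0, velocity_mm_s=10.0,
                     amplitude_fraction=0.8, half_width_mm=20.0),
            WaveSpec(onset_time_s=800.0, origin_mm=0.0, velocity_mm_s=8.0,
                     amplitude_fraction=0.7, half_width_mm=25.0),
            WaveSpec(onset_time_s=1300.0, origin_mm=0.0, velocity_mm_s=12.0,
                     amplitude_fraction=0.9, half_width_mm=18.0),
        ],
        breathing=Breathing(amplitude_mm=breathing_amplitude_mm, period_s=4.0),
        noise_sd=noise_sd,
        seed=seed,
    )
    return cfg, pressure_noise_sd_mmhg


@dataclass
class EventWindow:
    """Ground-truth bookkeeping for one simulated wave."""

    wave: WaveSpec
    enters_segment: bool
    t_enter_s: float | None
    t_exit_s: float | None
    sensor_arrival_s: list[float | None]


@dataclass
class PhantomGroundTruth:
    """True diameter field plus analytic event windows and sensor arrivals."""

    diameter_field_mm: np.ndarray  # (n_positions, n_frames)
    positions_mm: np.ndarray
    times_s: np.ndarray
    event_windows: list[EventWindow]
    sensor_positions_mm: np.ndarray


def _wave_factor(
    wave: WaveSpec, positions: np.ndarray, times: np.ndarray
) -> np.ndarray:
    """Multiplicative diameter factor of one wave on the (s, t) grid."""
    s = positions[:, None]
    t = times[None, :]
    centre = wave.origin_mm + wave.velocity_mm_s * (t - wave.onset_time_s)
    active = (t >= wave.onset_time_s) & (t <= wave.end_time_s)
    g = np.exp(-((s - centre) ** 2) / (2.0 * wave.half_width_mm**2))
    return 1.0 - wave.amplitude_fraction * g * active


def _background_factor(
    bg: BackgroundActivity, positions: np.ndarray, times: np.ndarray,
    duration_s: float, rng: np.random.Generator,
) -> np.ndarray:
    factor = np.ones((positions.size, times.size))
    n_events = rng.poisson(bg.rate_per_min * duration_s / 60.0)
    length = positions[-1] if positions.size else 0.0
    for _ in range(int(n_events)):
        s_c = rng.uniform(0.0, length)
        t_start = rng.uniform(0.0, duration_s)
        g = np.exp(-((positions - s_c) ** 2) / (2.0 * bg.width_mm**2))
        phase = (times - t_start) / bg.duration_s
        env = np.where(
            (phase >= 0) & (phase <= 1), np.sin(np.pi * np.clip(phase, 0, 1)) ** 2, 0.0
        )
        factor *= 1.0 - bg.amplitude_fraction * g[:, None] * env[None, :]
    return factor


def _event_window(
    wave: WaveSpec, seg_start: float, seg_end: float, duration_s: float,
    sensors: np.ndarray,
) -> EventWindow:
    v = wave.velocity_mm_s
    # times at which the trough centre crosses the segment ends
    t_a = wave.onset_time_s + (seg_start - wave.origin_mm) / v
    t_b = wave.onset_time_s + (seg_end - wave.origin_mm) / v
    t_in, t_out = min(t_a, t_b), max(t_a, t_b)
    t_in = max(t_in, wave.onset_time_s, 0.0)
    t_out = min(t_out, wave.end_time_s, duration_s)
    enters = t_in < t_out
    arrivals: list[float | None] = []
    for s_i in sensors:
        t_arr = wave.onset_time_s + (s_i - wave.origin_mm) / v
        ok = wave.onset_time_s <= t_arr <= min(wave.end_time_s, duration_s)
        arrivals.append(float(t_arr) if ok else None)
    return EventWindow(
        wave=wave,
        enters_segment=enters,
        t_enter_s=float(t_in) if enters else None,
        t_exit_s=float(t_out) if enters else None,
        sensor_arrival_s=arrivals,
    )


def simulate_diameter_field(config: PhantomConfig) -> PhantomGroundTruth:
    """Evaluate the ground-truth lumen diameter D(s, t) on the phantom grid.

    HAPC waves and randomly drawn background events multiply the baseline
    diameter; the result is clamped to ``[occlusion_floor, D0]``. Event
    windows (trough inside the imaged segment) and per-sensor arrival times
    are computed analytically from the wave parameters.
    """
    positions = config.positions_mm
    times = config.times_s
    d0 = config.baseline_diameter_mm

    factor = np.ones((positions.size, times.size))
    for wave in config.hapc_events:
        factor *= _wave_factor(wave, positions, times)
    if config.background_activity.rate_per_min > 0:
        factor *= _background_factor(
            config.background_activity, positions, times, config.duration_s,
            config.rng(stream=0),
        )
    d = np.clip(d0 * factor, config.occlusion_floor_mm, d0)

    sensors = np.asarray(config.sensor_positions_mm, dtype=float)
    seg_end = config.midline_arclength_mm
    windows = [
        _event_window(w, 0.0, seg_end, config.duration_s, sensors)
        for w in config.hapc_events
    ]
    for win in windows:
        if not win.enters_segment:
            warnings.warn(
                f"wave with onset {win.wave.onset_time_s} s never enters the imaged segment",
                stacklevel=2,
            )
    return PhantomGroundTruth(
        diameter_field_mm=d,
        positions_mm=positions,
        times_s=times,
        event_windows=windows,
        sensor_positions_mm=sensors,
    )


def _midline_geometry(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Densely resampled midline points and their arc-lengths (step = half pixel)."""
    pts = config.midline_points_mm
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    step = config.pixel_spacing_mm / 2.0
    s_fine = np.arange(0.0, arc[-1] + step / 2, step)
    x = np.interp(s_fine, arc, pts[:, 0])
    y = np.interp(s_fine, arc, pts[:, 1])
    return np.column_stack([x, y]), s_fine


def render_frames(truth: PhantomGroundTruth, config: PhantomConfig) -> ImageSeries:
    """Render the bright-lumen tube over a dark background for every frame.

    The tube edge is anti-aliased over one pixel so that the half-maximum
    intensity crossing lies at the true wall position. Breathing displaces
    the whole tube rigidly in the vertical (row) direction; zero-mean
    Gaussian noise of sd ``noise_sd`` is added last.

    Raises
    ------
    ValueError
        If the midline does not fit in the image with a margin of at least
        the baseline diameter, or if the tube leaves the field of view at
        any frame (the first offending frame is reported).
    """
    rows, cols = config.image_shape
    sp = config.pixel_spacing_mm
    extent_x = (cols - 1) * sp
    extent_y = (rows - 1) * sp
    pts = config.midline_points_mm
    d0 = config.baseline_diameter_mm
    if (
        pts[:, 0].min() < d0 or pts[:, 0].max() > extent_x - d0
        or pts[:, 1].min() < d0 or pts[:, 1].max() > extent_y - d0
    ):
        raise ValueError("midline must fit inside the image with margin >= baseline diameter")

    mid_pts, mid_s = _midline_geometry(config)
    tree = cKDTree(mid_pts)
    yy, xx = np.meshgrid(np.arange(rows) * sp, np.arange(cols) * sp, indexing="ij")
    dist_map, idx = tree.query(np.column_stack([xx.ravel(), yy.ravel()]))
    dist_map = dist_map.reshape(rows, cols)
    s_map = mid_s[idx].reshape(rows, cols)

    times = truth.times_s
    n_frames = times.size
    frames = np.empty((rows, cols, n_frames), dtype=np.float32)
    rng = config.rng(stream=1)
    lum, bkg = config.lumen_intensity, config.background_intensity
    row_idx, col_idx = np.mgrid[0:rows, 0:cols].astype(float)

    for k in range(n_frames):
        b = config.breathing.amplitude_mm * np.sin(
            2.0 * np.pi * times[k] / config.breathing.period_s
        )
        if b != 0.0:
            coords = np.array([row_idx - b / sp, col_idx])
            dist_k = ndimage.map_coordinates(dist_map, coords, order=1, mode="nearest")
            s_k = ndimage.map_coordinates(s_map, coords, order=1, mode="nearest")
        else:
            dist_k, s_k = dist_map, s_map
        d_here = np.interp(s_k.ravel(), truth.positions_mm, truth.diameter_field_mm[:, k])
        cover = np.clip((d_here.reshape(rows, cols) / 2.0 - dist_k) / sp + 0.5, 0.0, 1.0)
        frame = bkg + (lum - bkg) * cover
        border_max = max(
            frame[0, :].max(), frame[-1, :].max(), frame[:, 0].max(), frame[:, -1].max()
        )
        if border_max > bkg + 0.5 * (lum - bkg):
            raise ValueError(f"lumen tube exits the field of view at frame {k}")
        frames[:, :, k] = frame

    if config.noise_sd > 0:
        frames += rng.normal(0.0, config.noise_sd, size=frames.shape).astype(np.float32)
    return ImageSeries(
        data=frames,
        pixel_spacing_mm=sp,
        frame_interval_s=config.frame_interval_s,
    )


def simulate_manometry(
    truth: PhantomGroundTruth,
    config: PhantomConfig,
    sampling_rate_hz: float | None = None,
    noise_sd_mmhg: float = 0.0,
) -> PressureRecording:
    """Derive multi-channel pressure traces from the diameter field.

    Per channel at arc-length ``s_i``::

        P_i(t) = baseline + Pmax * max(0, 1 - D(s_i, t) / D0)**gamma + noise

    modelling port occlusion by the contracting wall. Channels are ordered
    proximal to distal. Sampling rate defaults to the imaging frame rate.
    """
    sensors = truth.sensor_positions_mm
    if sensors.size == 0:
        raise ValueError("no sensor positions configured")
    if sensors[0] < truth.positions_mm[0] or sensors[-1] > truth.positions_mm[-1]:
        raise ValueError("sensor positions outside the diameter-field range")

    if sampling_rate_hz is None:
        sampling_rate_hz = 1.0 / config.frame_interval_s
        times = truth.times_s
    else:
        n = int(np.floor(config.duration_s * sampling_rate_hz))
        times = np.arange(n) / sampling_rate_hz

    d0 = config.baseline_diameter_mm
    traces = np.empty((sensors.size, times.size))
    for i, s_i in enumerate(sensors):
        # linear interpolation in space, then in time if resampled
        w = np.clip(
            np.searchsorted(truth.positions_mm, s_i) - 1, 0, truth.positions_mm.size - 2
        )
        frac = (s_i - truth.positions_mm[w]) / (
            truth.positions_mm[w + 1] - truth.positions_mm[w]
        )
        d_i = (1 - frac) * truth.diameter_field_mm[w] + frac * truth.diameter_field_mm[w + 1]
        if times is not truth.times_s:
            d_i = np.interp(times, truth.times_s, d_i)
        occ = np.maximum(0.0, 1.0 - d_i / d0)
        traces[i] = (
            config.pressure_baseline_mmhg
            + config.pressure_gain_mmhg * occ**config.pressure_gamma
        )
    if noise_sd_mmhg > 0:
        traces += config.rng(stream=2).normal(0.0, noise_sd_mmhg, size=traces.shape)
    return PressureRecording(
        pressures_mmhg=traces,
        sampling_rate_hz=float(sampling_rate_hz),
        channel_positions_mm=sensors.astype(float),
        channel_labels=[f"ch{i + 1}" for i in range(sensors.size)],
    )
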