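"""Synthetic single-fly bioluminescence frame stacks with exported ground truth.

The simulator emulates the recording rig end to end: point-like glowing flies
confined to capillary tubes, a circadianly modulated and exponentially decaying
photon rate (luciferin depletion), one-dimensional movement within the tube,
rest/sleep bouts with circadian structure, and camera background with vignette,
shot noise and read noise.  Every random draw is tied to ``(seed, fly_id)`` so
flies are mutually independent and each stack is bit-reproducible.

Time is measured in hours since the start of recording, which is taken to be
subjective dusk (CT12): hours 0-12 of each cycle are subjective night and hours
12-24 subjective day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    BIN_HEIGHT_PX,
    N_BINS,
    TUBE_LENGTH_PX,
    TUBE_WIDTH_PX,
    TrayGeometry,
    build_geometry,
)

SCENARIOS = ("control", "clock_only", "arrhythmic")

#: frame states in ground truth
STATE_ACTIVE, STATE_REST, STATE_SLEEP = "active", "rest", "sleep"


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of one simulated recording.

    Behavioural bout means are modulated on a log scale: the instantaneous mean
    rest-bout length is ``rest_bout_s * exp(rest_mod * cos(...))`` peaking
    ``rest_peak_h`` hours after subjective dusk, and the mean active-bout
    length peaks twice per cycle (near dusk and dawn).  In the ``clock_only``
    scenario the behavioural modulations are switched off while the photon
    clock still cycles; in ``arrhythmic`` both are switched off.
    """

    n_days: float = 7.0
    frame_s: float = 300.0
    image_size: tuple[int, int] = (1024, 1024)  # (height, width)
    n_columns: int = 12
    n_rows: int = 4
    tube_length_px: int = TUBE_LENGTH_PX
    tube_width_px: int = TUBE_WIDTH_PX
    col_pitch_px: int = 32
    row_pitch_px: int = 240
    marker_positions: list[tuple[float, float]] | None = None

    # molecular clock
    period_h: float = 24.0
    clock_amplitude: float = 0.5
    clock_phase_h: float = 0.0  # rate peaks at dusk (t = 0) by default
    decay_halflife_h: float = 96.0
    base_photon_rate: float = 10.0  # counts/s attributable to the fly

    # behaviour
    behaviour_period_h: float | None = None  # defaults to period_h
    active_bout_s: float = 90.0
    rest_bout_s: float = 730.0
    activity_mod: float = 1.0
    rest_mod: float = 1.4
    rest_peak_h: float = 6.0
    walk_speed_bins_s: float = 1.0
    turn_prob: float = 0.03  # per-step direction-flip probability of the walk

    # optics / camera
    psf_sigma_px: float = 2.0
    background_level: float = 5.0  # counts per pixel per frame
    tube_glow: float = 0.12  # extra in-tube counts per pixel per frame
    vignette_gain: float = 0.3
    read_noise_sd: float = 1.0
    marker_counts: float = 20000.0  # photons per corner marker per frame
    rotation_deg: float = 0.0

    behaviour_scenario: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.behaviour_scenario not in SCENARIOS:
            raise ConfigError(
                f"unknown behaviour scenario {self.behaviour_scenario!r}; "
                f"expected one of {SCENARIOS}"
            )
        if not 0.0 <= self.clock_amplitude <= 1.0:
            raise ConfigError("clock_amplitude must lie in [0, 1]")
        for name in ("tube_length_px", "tube_width_px", "col_pitch_px",
                     "row_pitch_px"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_columns * self.n_rows > 48:
            raise ConfigError("a tray holds at most 48 tubes")
        if min(self.base_photon_rate, self.decay_halflife_h,
               self.period_h) <= 0:
            raise ConfigError("rate, half-life and period must be positive")

    @property
    def n_frames(self) -> int:
        # floor: every frame is fully covered by simulated behaviour
        return int(self.n_days * 86400.0 // self.frame_s)

    @property
    def n_flies(self) -> int:
        return self.n_columns * self.n_rows

    @property
    def effective_behaviour_period_h(self) -> float:
        return self.behaviour_period_h or self.period_h

    @property
    def effective_clock_amplitude(self) -> float:
        return 0.0 if self.behaviour_scenario == "arrhythmic" else self.clock_amplitude

    def frame_times_h(self) -> np.ndarray:
        """Circadian timestamps (hours since dusk) of frame midpoints."""
        return (np.arange(self.n_frames) + 0.5) * self.frame_s / 3600.0


def _fly_rng(config: SimConfig, fly_id: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, fly_id, stream])


@dataclass
class GroundTruth:
    """Per-fly ground truth exported alongside a rendered stack."""

    fly_id: int
    true_period_h: float
    behaviour_period_h: float
    # per-frame arrays
    time_active_s: np.ndarray
    time_rest_s: np.ndarray
    position_bin: np.ndarray  # fractional bin index in [0, 46)
    photon_rate: np.ndarray  # counts/s at the frame midpoint
    state: list[str]
    # clearly-visible sleep: rest bouts > 300 s occupying the majority of at
    # least two frames; spans are the majority-coverage frames
    sleep_episodes: list[tuple[int, int, float]]
    # every rest bout > 300 s with its full any-overlap frame span; a
    # frame-based detector may legitimately flag any of these as sleep even
    # when the bout lacks a two-frame majority signature
    sleep_bouts_any: list[tuple[int, int, float]] = field(default_factory=list)
    # rendering payload: per frame, list of (bin_position, seconds) deposits
    deposits: list[list[tuple[float, float]]] = field(repr=False, default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.time_active_s)

    def sleep_frames(self) -> np.ndarray:
        """Boolean per-frame mask of frames inside a true sleep episode."""
        mask = np.zeros(self.n_frames, dtype=bool)
        for s, e, _ in self.sleep_episodes:
            mask[s : e + 1] = True
        return mask

    def to_dict(self) -> dict:
        return {
            "fly_id": self.fly_id,
            "true_period_h": self.true_period_h,
            "behaviour_period_h": self.behaviour_period_h,
            "time_active_s": np.round(self.time_active_s, 3).tolist(),
            "time_rest_s": np.round(self.time_rest_s, 3).tolist(),
            "position_bin": np.round(self.position_bin, 3).tolist(),
            "photon_rate": np.round(self.photon_rate, 6).tolist(),
            "state": self.state,
            "sleep_episodes": [
                [int(s), int(e), float(d)] for s, e, d in self.sleep_episodes
            ],
            "sleep_bouts_any": [
                [int(s), int(e), float(d)] for s, e, d in self.sleep_bouts_any
            ],
        }


def _bout_mean_s(config: SimConfig, kind: str, t_h: float) -> float:
    """Instantaneous mean bout length of the alternating-renewal model."""
    tau = config.effective_behaviour_period_h
    modulated = config.behaviour_scenario == "control"
    if kind == "active":
        mod = config.activity_mod if modulated else 0.0
        # bimodal: activity bouts lengthen near subjective dusk and dawn
        return config.active_bout_s * np.exp(mod * np.cos(4 * np.pi * t_h / tau))
    mod = config.rest_mod if modulated else 0.0
    return config.rest_bout_s * np.exp(
        mod * np.cos(2 * np.pi * (t_h - config.rest_peak_h) / tau)
    )


def simulate_behaviour(config: SimConfig, fly_id: int) -> GroundTruth:
    """Simulate one fly's activity/rest bout trajectory and frame-level truth.

    The behaviour model is an alternating semi-Markov chain: exponentially
    distributed active and rest bouts whose mean lengths are sinusoidally
    modulated (on a log scale) in the ``control`` scenario.  Rest bouts longer
    than one frame (> ``frame_s``) are recorded as ground-truth sleep episodes.
    Within active bouts the fly performs a reflected random walk along the
    46-bin tube axis; per-frame dwell times per bin are kept for rendering.
    """
    rng = _fly_rng(config, fly_id)
    frame_s = config.frame_s
    n_frames = config.n_frames
    total_s = n_frames * frame_s  # simulate exactly the framed duration

    time_active = np.zeros(n_frames)
    time_rest = np.zeros(n_frames)
    deposits: list[list[tuple[float, float]]] = [[] for _ in range(n_frames)]
    rest_pos_weight = np.zeros(n_frames)
    rest_pos_sum = np.zeros(n_frames)
    path_pos_sum = np.zeros(n_frames)
    sleep_episodes: list[tuple[int, int, float]] = []
    sleep_bouts_any: list[tuple[int, int, float]] = []

    pos = float(rng.uniform(2.0, N_BINS - 2.0))
    t = 0.0
    active = rng.random() < 0.5
    while t < total_s:
        mean = _bout_mean_s(config, "active" if active else "rest", t / 3600.0)
        dur = float(rng.exponential(mean))
        end = min(t + dur, total_s)
        if active:
            # reflected persistent (run-and-tumble) walk: unit-bin steps at
            # walk_speed steps/s whose direction flips with prob turn_prob.
            # Persistence produces the flat, rectangular smear of a fly
            # running along the tube; a diffusive walk would pile dwell time
            # into rest-like lumps.
            n_steps = max(1, int(round((end - t) * config.walk_speed_bins_s)))
            flips = np.where(rng.random(n_steps) < config.turn_prob, -1.0, 1.0)
            flips[0] = rng.choice((-1.0, 1.0))
            steps = np.cumprod(flips)
            path = pos + np.cumsum(steps)
            # reflect into [0.5, N_BINS - 0.5]
            span = N_BINS - 1.0
            path = 0.5 + np.abs((path - 0.5) % (2 * span) - span)
            step_dt = (end - t) / n_steps
            step_t = t + (np.arange(n_steps) + 0.5) * step_dt
            step_frame = np.minimum((step_t // frame_s).astype(int), n_frames - 1)
            for f in np.unique(step_frame):
                sel = step_frame == f
                # exact bout-frame overlap; the quantized steps only decide
                # how the photons are spread along the tube
                ov = min(end, (f + 1) * frame_s) - max(t, f * frame_s)
                time_active[f] += ov
                path_pos_sum[f] += float(path[sel].mean()) * ov
                bins, counts = np.unique(np.round(path[sel]), return_counts=True)
                scale = ov / (np.count_nonzero(sel) * step_dt)
                for b, c in zip(bins, counts):
                    deposits[f].append((float(b), float(c * step_dt * scale)))
            pos = float(path[-1])
        else:
            f0 = int(t // frame_s)
            f1 = min(int((end - 1e-9) // frame_s), n_frames - 1)
            for f in range(f0, f1 + 1):
                ov = min(end, (f + 1) * frame_s) - max(t, f * frame_s)
                if ov <= 0:
                    continue
                time_rest[f] += ov
                rest_pos_sum[f] += pos * ov
                rest_pos_weight[f] += ov
                deposits[f].append((pos, float(ov)))
            if end - t > frame_s:
                sleep_bouts_any.append((f0, f1, float(end - t)))
                # export as clearly-visible sleep only when the bout occupies
                # the majority of at least two frames: a bout that merely
                # clips frame edges has no stable-position signature at frame
                # resolution
                maj = [f for f in range(f0, f1 + 1)
                       if (min(end, (f + 1) * frame_s) - max(t, f * frame_s))
                       >= frame_s / 2.0]
                if len(maj) >= 2:
                    sleep_episodes.append((maj[0], maj[-1], float(end - t)))
        t = end
        active = not active

    with np.errstate(invalid="ignore"):
        position = np.where(
            rest_pos_weight > 0,
            rest_pos_sum / np.maximum(rest_pos_weight, 1e-12),
            path_pos_sum / np.maximum(time_active, 1e-12),
        )
    sleep_mask = np.zeros(n_frames, dtype=bool)
    for s, e, _ in sleep_episodes:
        sleep_mask[s : e + 1] = True
    state = [
        STATE_SLEEP if sleep_mask[f] and time_rest[f] >= frame_s / 2
        else (STATE_REST if time_rest[f] >= frame_s / 2 else STATE_ACTIVE)
        for f in range(n_frames)
    ]
    rate = simulate_clock(config, fly_id)
    return GroundTruth(
        fly_id=fly_id,
        true_period_h=config.period_h,
        behaviour_period_h=config.effective_behaviour_period_h,
        time_active_s=time_active,
        time_rest_s=time_rest,
        position_bin=position,
        photon_rate=rate,
        state=state,
        sleep_episodes=sleep_episodes,
        sleep_bouts_any=sleep_bouts_any,
        deposits=deposits,
    )


def simulate_clock(config: SimConfig, fly_id: int = 0,
                   t_h: np.ndarray | None = None) -> np.ndarray:
    """Photon rate (counts/s) of the fly's clock reporter at frame midpoints.

    ``rate(t) = base * 2**(-t / halflife) * (1 + A cos(2 pi (t - phase) / tau))``
    with the phase chosen so the signal peaks at subjective dusk (t = 0) and is
    lowest at subjective dawn.  An infinite half-life gives a stationary
    sinusoid about the base rate.
    """
    if t_h is None:
        t_h = config.frame_times_h()
    t_h = np.asarray(t_h, dtype=float)
    amp = config.effective_clock_amplitude
    decay = np.where(
        np.isfinite(config.decay_halflife_h),
        2.0 ** (-t_h / config.decay_halflife_h),
        1.0,
    )
    cyc = 1.0 + amp * np.cos(
        2 * np.pi * (t_h - config.clock_phase_h) / config.period_h
    )
    return config.base_photon_rate * decay * cyc


def tray_layout(config: SimConfig) -> tuple[TrayGeometry, list[tuple[float, float]]]:
    """True tray geometry for a config, plus the three corner marker points.

    Tubes are laid out on a regular grid centred in the image; markers sit at
    the top-left, top-right and bottom-left corners of the tray bounding box.
    """
    h, w = config.image_size
    total_w = (config.n_columns - 1) * config.col_pitch_px
    total_h = (config.n_rows - 1) * config.row_pitch_px + config.tube_length_px
    x0 = (w - total_w) / 2.0
    y0 = int(round((h - total_h) / 2.0))
    centers = x0 + np.arange(config.n_columns) * config.col_pitch_px
    row_tops = y0 + np.arange(config.n_rows) * config.row_pitch_px
    margin = 14.0
    bx0 = centers[0] - TUBE_WIDTH_PX // 2 - margin
    bx1 = centers[-1] + TUBE_WIDTH_PX // 2 + margin
    by0 = row_tops[0] - margin
    by1 = row_tops[-1] + config.tube_length_px - 1 + margin
    if bx0 < 0 or by0 < 0 or bx1 > w - 1 or by1 > h - 1:
        raise ConfigError(
            f"tray (markers included) does not fit the {h}x{w} image; "
            "enlarge image_size or shrink the layout"
        )
    markers = config.marker_positions or [(bx0, by0), (bx1, by0), (bx0, by1)]
    geom = build_geometry(
        centers, row_tops, tube_length_px=config.tube_length_px,
        marker_points=[tuple(map(float, p)) for p in markers],
        rotation_deg=0.0,
    )
    return geom, list(geom.marker_points)


def _gaussian_patch(shape: tuple[int, int], cy: float, cx: float,
                    sigma: float, total: float, out: np.ndarray) -> None:
    """Add a normalised Gaussian spot carrying ``total`` counts in place.

    The kernel is evaluated on a +/-4 sigma window and renormalised to sum to
    ``total`` exactly, so photons are conserved regardless of truncation.
    """
    r = max(2, int(np.ceil(4 * sigma)))
    yi0, yi1 = int(np.floor(cy)) - r, int(np.floor(cy)) + r + 1
    xi0, xi1 = int(np.floor(cx)) - r, int(np.floor(cx)) + r + 1
    yi0c, yi1c = max(yi0, 0), min(yi1, shape[0])
    xi0c, xi1c = max(xi0, 0), min(xi1, shape[1])
    if yi0c >= yi1c or xi0c >= xi1c:
        return
    yy = np.arange(yi0c, yi1c, dtype=float) - cy
    xx = np.arange(xi0c, xi1c, dtype=float) - cx
    ky = np.exp(-0.5 * (yy / sigma) ** 2)
    kx = np.exp(-0.5 * (xx / sigma) ** 2)
    patch = np.outer(ky, kx)
    s = patch.sum()
    if s <= 0:
        return
    out[yi0c:yi1c, xi0c:xi1c] += patch * (total / s)


@dataclass
class RenderedStack:
    """A rendered stack plus everything needed to validate the pipeline."""

    stack: np.ndarray  # (n_frames, H, W) uint16
    geometry: TrayGeometry  # geometry of the *aligned* (unrotated) tray
    markers_in_frame: list[tuple[float, float]]  # marker points as rendered
    truths: list[GroundTruth]
    config: SimConfig
    saturated: bool = False

    def frame_times_h(self) -> np.ndarray:
        return self.config.frame_times_h()


def render_stack(config: SimConfig,
                 truths: list[GroundTruth] | None = None,
                 noise: bool = True, quantize: bool = True) -> RenderedStack:
    """Render a 16-bit frame stack from per-fly ground truths.

    A resting fly deposits ``rate * rest_seconds`` photons in a Gaussian spot
    at its position; an active fly spreads its photons along the bins visited
    by its within-frame walk (the characteristic smear).  The camera model
    adds a vignette-scaled background, a faint uniform in-tube glow (scatter
    from the tube glass and food plug), three bright corner markers, Poisson
    shot noise and Gaussian read noise, then clips to the 16-bit range.  A
    non-zero ``config.rotation_deg`` rotates every frame about the image
    centre to exercise the alignment step.

    ``quantize=False`` returns float32 frames instead of uint16; Poisson shot
    noise already digitizes counts without bias, but in noise-free renders
    plain rounding systematically drops sub-count PSF tails, so quantitative
    photon-conservation work should use the float path.
    """
    from .preprocess import rotate_frame, rotate_points  # local: avoid cycle

    geom, markers = tray_layout(config)
    if truths is None:
        truths = [simulate_behaviour(config, i) for i in range(config.n_flies)]
    if len(truths) != geom.n_tubes:
        raise ConfigError("one ground truth required per tube")

    h, w = config.image_size
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((yy - h / 2.0) ** 2 + (xx - w / 2.0) ** 2) / ((h / 2.0) ** 2 + (w / 2.0) ** 2)
    vignette = 1.0 - config.vignette_gain * r2
    static = (config.background_level * vignette).astype(np.float64)
    for t in geom.tube_rects:
        ys, xs = t.slices()
        static[ys, xs] += config.tube_glow
    for mx, my in markers:
        _gaussian_patch((h, w), my, mx, 1.5, config.marker_counts, static)

    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 0xCA11])
    dtype = np.uint16 if quantize else np.float32
    stack = np.empty((config.n_frames, h, w), dtype=dtype)
    saturated = False
    for f in range(config.n_frames):
        frame = static.copy()
        for tube, truth in zip(geom.tube_rects, truths):
            rate = truth.photon_rate[f]
            cx = 0.5 * (tube.x_min + tube.x_max)
            for pos, seconds in truth.deposits[f]:
                cy = tube.y_min + (pos + 0.5) * BIN_HEIGHT_PX - 0.5
                _gaussian_patch(
                    (h, w), cy, cx, config.psf_sigma_px, rate * seconds, frame
                )
        if noise:
            frame = rng.poisson(np.maximum(frame, 0.0)).astype(np.float64)
            frame += rng.normal(0.0, config.read_noise_sd, size=frame.shape)
        if config.rotation_deg:
            frame = rotate_frame(frame, config.rotation_deg)
        if frame.max() > 65535.0:
            saturated = True
        if quantize:
            stack[f] = np.clip(np.round(frame), 0, 65535).astype(np.uint16)
        else:
            stack[f] = np.clip(frame, 0, 65535).astype(np.float32)
    if saturated:
        warnings.warn("rendered photon counts exceed the 16-bit range; "
                      "frames were clipped", stacklevel=2)
    markers_in_frame = rotate_points(markers, config.rotation_deg, (h, w)) \
        if config.rotation_deg else list(markers)
    return RenderedStack(
        stack=stack, geometry=geom, markers_in_frame=markers_in_frame,
        truths=truths, config=config, saturated=saturated,
    )


# ---------------------------------------------------------------------------
# series-level simulation (no imaging): used for rhythm/cohort studies
# ---------------------------------------------------------------------------

def simulate_fly_series(config: SimConfig, fly_id: int,
                        measurement_noise: bool = True) -> dict:
    """Ground-truth-level 30-min binned series for one fly.

    Skips rendering and measures the generative model directly: binned
    bioluminescence photon counts (Poisson-distributed around
    ``rate * frame_s`` when ``measurement_noise``), percent time active, and
    sleep consolidation built from the true sleep episodes.  Used to study the
    rhythm statistics at scales where rendering full image stacks would be
    wasteful.
    """
    from .sleep import bin_30min  # local import to avoid a cycle

    truth = simulate_behaviour(config, fly_id)
    n = truth.n_frames - truth.n_frames % 6
    counts = truth.photon_rate[:n] * config.frame_s
    if measurement_noise:
        rng = _fly_rng(config, fly_id, stream=1)
        counts = rng.poisson(counts).astype(float)
    consol = np.zeros(n)
    for s, e, d in truth.sleep_episodes:
        if s < n:
            consol[s : min(e, n - 1) + 1] = d / 60.0
    pct_active = bin_30min(truth.time_active_s[:n], "sum").values / 1800.0 * 100.0
    return {
        "truth": truth,
        "clock": bin_30min(counts, "sum"),
        "locomotor": bin_30min(truth.time_active_s[:n], "sum",
                               as_percent_of=1800.0),
        "consolidation": bin_30min(consol, "nonzero_mean"),
        "pct_active": pct_active,
    }


def simulate_cohort(
    base_config: SimConfig,
    n_flies: int,
    period_mean_h: float = 24.0,
    period_sd_h: float = 0.8,
    couple_periods: bool = True,
    seed: int | None = None,
) -> list[dict]:
    """Simulate a cohort with per-fly circadian periods.

    Each fly draws a molecular-clock period from N(mean, sd).  When
    ``couple_periods`` the behavioural oscillator shares the fly's clock
    period (a common per-fly period modifier); otherwise the behavioural
    period is drawn independently from the same distribution, decoupling the
    two oscillators.
    """
    seed = base_config.seed if seed is None else seed
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xC0407])
    flies = []
    for i in range(n_flies):
        clock_tau = float(rng.normal(period_mean_h, period_sd_h))
        beh_tau = clock_tau if couple_periods else float(
            rng.normal(period_mean_h, period_sd_h)
        )
        cfg = replace(base_config, period_h=clock_tau,
                      behaviour_period_h=beh_tau, seed=seed)
        flies.append(simulate_fly_series(cfg, i))
    return flies
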