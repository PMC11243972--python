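"""FMCW radar scene simulator for non-contact respiration sensing.

A 77 GHz frequency-modulated continuous-wave (FMCW) radar transmits linear
chirps; mixing each echo with the transmitted chirp yields an intermediate
frequency (IF) tone whose frequency encodes target range and whose *phase*
encodes sub-wavelength radial motion with sensitivity ``4*pi/lambda`` radians
per metre.  Chest-wall displacement during breathing (a few millimetres at
0.1-0.5 Hz) is therefore visible as a slow-time phase modulation of the IF
signal at the thorax range bin.

This module generates multi-antenna IF data cubes from first principles:

* a chest-displacement model — a repeated raised ``sin^p`` arch of
  configurable amplitude, rate and shape, optionally interrupted by apnoea
  (breath-holding) intervals;
* the dechirped IF signal model for point reflectors, including the
  range-dependent beat frequency and the residual video phase term;
* static clutter reflectors, complex white receiver noise at a prescribed
  SNR, and per-channel phase offsets / slow-time lags emulating an
  uncalibrated four-channel receiver.

The simulated cubes are the canonical input for the downstream processing
chain (:mod:`respiradar.vitals_dsp`) and for the classification experiments.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = [
    "C0",
    "RadarConfig",
    "PatternClass",
    "BreathingPattern",
    "SceneConfig",
    "IFDataCube",
    "DisplacementTrace",
    "respiratory_displacement",
    "pattern_presets",
    "if_sample",
    "synthesize_cube",
    "displacement_trace",
    "save_cube",
    "load_cube",
]

#: Speed of light [m/s].
C0 = 299_792_458.0


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RadarConfig:
    """Chirp/frame timing and geometry of the FMCW radar.

    Defaults follow the reference profile of a 77 GHz automotive-band
    vital-sign radar: 4 GHz sweep in 50 us, 200 fast-time samples per chirp,
    2 chirps per 50 ms frame, four receive channels.
    """

    carrier_frequency: float = 77e9   # fc [Hz]
    bandwidth: float = 4e9            # B  [Hz]
    chirp_duration: float = 50e-6     # T  [s]
    samples_per_chirp: int = 200
    chirps_per_frame: int = 2
    frame_duration: float = 50e-3     # [s]
    n_rx: int = 4

    def __post_init__(self) -> None:
        for name in ("carrier_frequency", "bandwidth", "chirp_duration",
                     "frame_duration"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.samples_per_chirp < 2:
            raise ValueError("samples_per_chirp must be >= 2")
        if self.chirps_per_frame < 1 or self.n_rx < 1:
            raise ValueError("chirps_per_frame and n_rx must be >= 1")
        if self.chirps_per_frame * self.chirp_duration > self.frame_duration:
            raise ValueError("chirps do not fit inside one frame")

    @property
    def wavelength(self) -> float:
        """Carrier wavelength lambda = c/fc [m]."""
        return C0 / self.carrier_frequency

    @property
    def slope(self) -> float:
        """FM slope S = B/T [Hz/s]."""
        return self.bandwidth / self.chirp_duration

    @property
    def fast_time_rate(self) -> float:
        """ADC sampling rate within a chirp [Hz]."""
        return self.samples_per_chirp / self.chirp_duration

    @property
    def slow_time_rate(self) -> float:
        """Frame rate, i.e. the slow-time sampling rate [Hz]."""
        return 1.0 / self.frame_duration

    @property
    def range_bin_spacing(self) -> float:
        """Range resolution c/(2B) of an unpadded fast-time FFT [m]."""
        return C0 / (2.0 * self.bandwidth)

    def config_dict(self) -> dict:
        return {
            "carrier_frequency": self.carrier_frequency,
            "bandwidth": self.bandwidth,
            "chirp_duration": self.chirp_duration,
            "samples_per_chirp": self.samples_per_chirp,
            "chirps_per_frame": self.chirps_per_frame,
            "frame_duration": self.frame_duration,
            "n_rx": self.n_rx,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RadarConfig":
        return cls(**d)


class PatternClass(str, enum.Enum):
    """The four breathing patterns distinguished by the system."""

    NORMAL = "normal"
    SLOW_DEEP = "slow_deep"
    QUICK = "quick"
    MENINGITIC = "meningitic"


@dataclass(frozen=True)
class BreathingPattern:
    """Parameters of the periodic chest-displacement model.

    ``amplitude`` (Ar) scales the arch, ``rate`` (fr) is the breathing
    frequency, and ``shape_exponent`` (p) controls how rounded the peaks
    are; ``p = 2`` makes the displacement an exact sinusoid at ``rate``.
    ``apnoea_schedule`` lists ``(start, duration)`` breath-holding
    intervals in seconds (meningitic breathing); during apnoea the chest
    holds the position it had at apnoea onset and the breathing cycle
    resumes continuously afterwards.
    """

    pattern_class: PatternClass
    amplitude: float = 0.004          # Ar [m]
    rate: float = 0.28                # fr [Hz]
    shape_exponent: float = 2.0       # p  [-]
    apnoea_schedule: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if not (self.rate > 0 and self.amplitude > 0 and self.shape_exponent > 0):
            raise ValueError("rate, amplitude and shape_exponent must be positive")
        sched = tuple(sorted(tuple(map(float, iv)) for iv in self.apnoea_schedule))
        object.__setattr__(self, "apnoea_schedule", sched)
        prev_end = -math.inf
        for start, dur in sched:
            if dur <= 0 or start < 0:
                raise ValueError("apnoea intervals need start >= 0 and duration > 0")
            if start < prev_end:
                raise ValueError("apnoea intervals must not overlap")
            prev_end = start + dur

    def config_dict(self) -> dict:
        return {
            "pattern_class": self.pattern_class.value,
            "amplitude": self.amplitude,
            "rate": self.rate,
            "shape_exponent": self.shape_exponent,
            "apnoea_schedule": [list(iv) for iv in self.apnoea_schedule],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BreathingPattern":
        d = dict(d)
        d["pattern_class"] = PatternClass(d["pattern_class"])
        d["apnoea_schedule"] = tuple(tuple(iv) for iv in d.get("apnoea_schedule", ()))
        return cls(**d)


@dataclass(frozen=True)
class SceneConfig:
    """Geometry and disturbance model of a simulated measurement.

    ``rx_phase_offsets`` / ``rx_delays`` model the unknown per-channel
    phase offsets and integer slow-time lags of the receive chains; when
    ``None`` they are drawn from / set to defaults by
    :func:`synthesize_cube` using ``seed``.
    """

    target_range: float = 0.8                         # [m]
    clutter: tuple[tuple[float, float], ...] = ()     # (range [m], reflectivity)
    snr_db: float = math.inf
    rx_phase_offsets: tuple[float, ...] | None = None  # [rad] per channel
    rx_delays: tuple[int, ...] | None = None           # slow-time lags per channel
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.target_range > 0:
            raise ValueError("target_range must be positive")
        for rng_m, refl in self.clutter:
            if rng_m <= 0 or refl < 0:
                raise ValueError("clutter needs positive range, reflectivity >= 0")

    def config_dict(self) -> dict:
        return {
            "target_range": self.target_range,
            "clutter": [list(c) for c in self.clutter],
            "snr_db": self.snr_db,
            "rx_phase_offsets": (None if self.rx_phase_offsets is None
                                 else list(self.rx_phase_offsets)),
            "rx_delays": None if self.rx_delays is None else list(self.rx_delays),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        d["clutter"] = tuple(tuple(c) for c in d.get("clutter", ()))
        if d.get("rx_phase_offsets") is not None:
            d["rx_phase_offsets"] = tuple(d["rx_phase_offsets"])
        if d.get("rx_delays") is not None:
            d["rx_delays"] = tuple(d["rx_delays"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class IFDataCube:
    """Complex IF samples indexed ``(frame, chirp, fast-time sample, rx)``."""

    samples: np.ndarray
    radar_config: RadarConfig
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        rc = self.radar_config
        f, c, n, r = self.samples.shape
        if (c, n, r) != (rc.chirps_per_frame, rc.samples_per_chirp, rc.n_rx):
            raise ValueError(
                f"cube shape {self.samples.shape} inconsistent with radar config "
                f"(expected (*, {rc.chirps_per_frame}, {rc.samples_per_chirp}, {rc.n_rx}))")
        if len(self.timestamps) != f:
            raise ValueError("one timestamp per frame required")
        dt = np.diff(self.timestamps)
        if f > 1 and not (np.all(dt > 0)
                          and np.allclose(dt, rc.frame_duration, rtol=1e-9)):
            raise ValueError("timestamps must increase by frame_duration")

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]


@dataclass
class DisplacementTrace:
    """Chest displacement sampled on the slow-time grid."""

    values: np.ndarray          # [m]
    sampling_rate: float        # [Hz]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("displacement values must be finite")


# ---------------------------------------------------------------------------
# Respiratory motion model
# ---------------------------------------------------------------------------

def respiratory_displacement(t, pattern: BreathingPattern):
    """Chest displacement ``xr(t)`` of the periodic breathing model [m].

    One breathing cycle on ``0 <= t' <= 1/fr`` is
    ``Ar * (0.5 - sin(pi * fr * t')**p)``; the cycle repeats by wrapping
    ``t`` modulo ``1/fr``.  For ``p = 2`` this reduces to
    ``(Ar/2) * cos(2*pi*fr*t)``, a pure tone at the breathing rate.

    Apnoea intervals pause the breathing clock: within ``[start,
    start+duration)`` the displacement stays at its onset value, and the
    cycle resumes continuously afterwards (the chest neither jumps nor
    teleports around a breath-hold).

    Parameters
    ----------
    t : float or array-like
        Time(s) in seconds, ``t >= 0``.
    pattern : BreathingPattern

    Returns
    -------
    float or ndarray of float
        Displacement in metres, bounded by ``[-0.5*Ar, 0.5*Ar]`` for
        ``p = 2`` (and by ``[Ar*(0.5-1), 0.5*Ar]`` generally).
    """
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("t must be finite")
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")

    # Breathing clock: pauses accumulate over apnoea intervals, freezing the
    # phase of the cycle at apnoea onset.
    paused = np.zeros_like(t_arr)
    for start, dur in pattern.apnoea_schedule:
        paused += np.clip(t_arr - start, 0.0, dur)
    tau = t_arr - paused

    fr = pattern.rate
    u = tau - np.floor(tau * fr) / fr       # tau modulo 1/fr
    x = pattern.amplitude * (0.5 - np.sin(np.pi * fr * u) ** pattern.shape_exponent)
    return float(x) if np.isscalar(t) or np.ndim(t) == 0 else x


#: Default chest-displacement amplitude for normal breathing [m].  Resting
#: adult chest-wall excursion is a few millimetres; 4 mm is used as the
#: baseline around which the class presets scale.
BASELINE_AMPLITUDE = 0.004

#: Preset parameter ranges per breathing-pattern class.  Rates follow the
#: resting-adult band (12-20 breaths/min) for normal breathing, with the
#: slow/deep and quick classes pushed to the band edges; amplitudes scale
#: relative to the normal baseline (deep breathing moves the chest more,
#: rapid shallow breathing less).  All values are package choices exposed
#: here for overriding.
PRESET_RANGES: dict[PatternClass, dict] = {
    PatternClass.NORMAL: {"rate": (0.20, 0.33), "amp_scale": (0.8, 1.2)},
    PatternClass.SLOW_DEEP: {"rate": (0.10, 0.15), "amp_scale": (1.5, 2.5)},
    PatternClass.QUICK: {"rate": (0.40, 0.50), "amp_scale": (0.6, 1.0)},
    PatternClass.MENINGITIC: {"rate": (0.20, 0.33), "amp_scale": (0.8, 1.2)},
}

#: Meningitic apnoea generator: breath-holds of 4-8 s recurring every
#: 10-15 s (onset-to-onset).
APNOEA_DURATION = (4.0, 8.0)
APNOEA_PERIOD = (10.0, 15.0)


def pattern_presets(pattern_class: PatternClass | str, seed: int, *,
                    duration: float = 25.0,
                    baseline_amplitude: float = BASELINE_AMPLITUDE,
                    ranges: dict | None = None) -> BreathingPattern:
    """Draw a :class:`BreathingPattern` from class-specific parameter ranges.

    ``duration`` bounds the generated apnoea schedule for meningitic
    breathing; other classes get an empty schedule.
    """
    pattern_class = PatternClass(pattern_class)
    spec = (ranges or PRESET_RANGES)[pattern_class]
    rng = np.random.default_rng(seed)

    rate = rng.uniform(*spec["rate"])
    amplitude = baseline_amplitude * rng.uniform(*spec["amp_scale"])
    shape_exponent = rng.uniform(1.6, 2.6)   # mild peak-shape variation

    schedule: list[tuple[float, float]] = []
    if pattern_class is PatternClass.MENINGITIC:
        onset = rng.uniform(3.0, 7.0)
        while onset < duration - 2.0:
            hold = rng.uniform(*APNOEA_DURATION)
            hold = min(hold, duration - onset)
            schedule.append((onset, hold))
            onset += rng.uniform(*APNOEA_PERIOD)

    return BreathingPattern(pattern_class=pattern_class, amplitude=amplitude,
                            rate=rate, shape_exponent=shape_exponent,
                            apnoea_schedule=tuple(schedule))


# ---------------------------------------------------------------------------
# IF signal model
# ---------------------------------------------------------------------------

def if_sample(t, range_now, radar: RadarConfig, amplitude=1.0):
    """Dechirped IF sample(s) of a point reflector.

    For round-trip delay ``td = 2*range_now/c`` the mixer output at
    fast-time ``t`` within a chirp is

        ``A * exp(-1j * (2*pi*fc*td + 2*pi*(B/T)*t*td - pi*(B/T)*td**2))``

    i.e. a beat tone at ``S*td`` whose constant phase term ``2*pi*fc*td``
    carries the displacement information (``-pi*S*td**2`` is the residual
    video phase).  Arguments broadcast.
    """
    range_now = np.asarray(range_now, dtype=float)
    if np.any(range_now <= 0):
        raise ValueError("range_now must be positive")
    td = 2.0 * range_now / C0
    s = radar.slope
    fc = radar.carrier_frequency
    phase = 2 * np.pi * fc * td + 2 * np.pi * s * np.asarray(t) * td - np.pi * s * td ** 2
    return amplitude * np.exp(-1j * phase)


def displacement_trace(pattern: BreathingPattern, duration: float,
                       sampling_rate: float) -> DisplacementTrace:
    """Sample the displacement model on a uniform grid."""
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    return DisplacementTrace(values=np.asarray(respiratory_displacement(t, pattern)),
                             sampling_rate=sampling_rate)


def synthesize_cube(pattern: BreathingPattern, scene: SceneConfig,
                    radar: RadarConfig, duration: float) -> IFDataCube:
    """Simulate a multi-antenna IF data cube for a breathing target.

    The target sits at ``scene.target_range + xr(t)`` with ``xr`` the
    respiratory displacement evaluated at the start of each chirp
    (respiration is quasi-static over one 50 us chirp).  Stationary clutter
    reflectors add fixed beat tones, receiver noise is complex circular
    Gaussian calibrated so that the per-sample target-echo SNR equals
    ``scene.snr_db``, and each receive channel gets a constant phase offset
    and an integer slow-time lag.  Everything is reproducible from
    ``scene.seed``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_frames = int(round(duration / radar.frame_duration))
    if n_frames < 1:
        raise ValueError("duration shorter than one frame")

    rng = np.random.default_rng(scene.seed)
    if scene.rx_phase_offsets is None:
        offsets = rng.uniform(-np.pi, np.pi, size=radar.n_rx)
    else:
        if len(scene.rx_phase_offsets) != radar.n_rx:
            raise ValueError("rx_phase_offsets length must equal n_rx")
        offsets = np.asarray(scene.rx_phase_offsets, dtype=float)
    if scene.rx_delays is None:
        delays = np.zeros(radar.n_rx, dtype=int)
    else:
        if len(scene.rx_delays) != radar.n_rx:
            raise ValueError("rx_delays length must equal n_rx")
        delays = np.asarray(scene.rx_delays, dtype=int)

    frame_t = np.arange(n_frames) * radar.frame_duration
    chirp_t = np.arange(radar.chirps_per_frame) * radar.chirp_duration
    # Chirp start times per (frame, chirp, rx); per-channel slow-time lags
    # shift the motion seen by that channel by whole frames.
    t_slow = (frame_t[:, None, None] + chirp_t[None, :, None]
              - delays[None, None, :] * radar.frame_duration)
    t_slow = np.clip(t_slow, 0.0, None)

    ranges = scene.target_range + respiratory_displacement(t_slow, pattern)
    t_fast = np.arange(radar.samples_per_chirp) / radar.fast_time_rate

    # (frame, chirp, sample, rx)
    echo = if_sample(t_fast[None, None, :, None], ranges[:, :, None, :], radar)
    target_power = float(np.mean(np.abs(echo) ** 2))
    for rng_m, refl in scene.clutter:
        echo = echo + if_sample(t_fast[None, None, :, None], rng_m, radar,
                                amplitude=refl)
    echo = echo * np.exp(1j * offsets)[None, None, None, :]

    if np.isfinite(scene.snr_db):
        noise_power = target_power / 10.0 ** (scene.snr_db / 10.0)
        sigma = math.sqrt(noise_power / 2.0)
        noise = rng.normal(scale=sigma, size=echo.shape + (2,))
        echo = echo + noise[..., 0] + 1j * noise[..., 1]

    return IFDataCube(samples=echo, radar_config=radar, timestamps=frame_t)


# ---------------------------------------------------------------------------
# Cube container I/O (HDF5)
# ---------------------------------------------------------------------------

def save_cube(cube: IFDataCube, path) -> None:
    """Write a cube to an HDF5 container (/samples complex64, config attrs)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=cube.samples.astype(np.complex64))
        f.create_dataset("timestamps", data=cube.timestamps)
        for key, val in cube.radar_config.config_dict().items():
            f.attrs[key] = val


def load_cube(path) -> IFDataCube:
    with h5py.File(path, "r") as f:
        samples = f["samples"][()]
        timestamps = f["timestamps"][()]
        cfg = RadarConfig.from_dict({k: (int(v) if isinstance(v, np.integer) else float(v))
                                     for k, v in f.attrs.items()})
    return IFDataCube(samples=samples, radar_config=cfg, timestamps=timestamps)
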