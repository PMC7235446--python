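"""Synthetic spike-train and event-stream generators plus event preprocessing.

Everything the training loops consume can be generated here: Poisson spike
trains, the slow pseudo-target traces for the regression task (a ramp and two
sinusoids), and a small DVS-like moving-bar event stream for gesture-style
classification.  A dynamic vision sensor emits (t, x, y, polarity) events on
local intensity changes; a bright bar sweeping across the sensor produces ON
events at its leading edge and OFF events at its trailing edge.  The
preprocessing mirrors event-camera conventions: sum events into fixed-width
time bins per polarity channel, sum neighbouring pixels to downsample, and cut
random fixed-length slices out of longer recordings.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EventStream",
    "poisson_spike_train",
    "regression_targets",
    "moving_bar_events",
    "MOVING_BAR_CLASSES",
    "bin_events",
    "slice_sequence",
]

ON, OFF = 1, 0

#: class id -> (axis, direction): sweep along x or y, in + or - direction.
#: Each class sweeps its own half of the sensor (entry side), so the classes
#: differ in their time-averaged pixel occupancy, not only in motion phase.
MOVING_BAR_CLASSES = {
    0: ("x", +1),  # left -> right, over the left half
    1: ("x", -1),  # right -> left, over the right half
    2: ("y", +1),  # top -> bottom, over the top half
    3: ("y", -1),  # bottom -> top, over the bottom half
}


@dataclass
class EventStream:
    """Sparse polarity events from a (height x width) sensor.

    ``t`` is in ms (float, non-decreasing after ``sort``), ``x``/``y`` are
    column/row indices, ``p`` is 1 for ON and 0 for OFF.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    p: np.ndarray
    width: int
    height: int
    duration: float  # ms

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.p) == n):
            raise ValueError("event fields must have equal length")
        if n and (self.x.min() < 0 or self.x.max() >= self.width
                  or self.y.min() < 0 or self.y.max() >= self.height):
            raise ValueError("event coordinates outside sensor geometry")

    def __len__(self) -> int:
        return len(self.t)

    def sort(self) -> "EventStream":
        """Return a copy with events in non-decreasing time order (stable)."""
        order = np.argsort(self.t, kind="stable")
        return EventStream(self.t[order], self.x[order], self.y[order],
                           self.p[order], self.width, self.height, self.duration)

    def to_text(self, path) -> None:
        """Write one ``t,x,y,p`` line per event (plain text, header comment)."""
        with open(path, "w") as fh:
            fh.write(f"# width={self.width} height={self.height} duration={self.duration}\n")
            for t, x, y, p in zip(self.t, self.x, self.y, self.p):
                fh.write(f"{t:.6g},{x},{y},{p}\n")

    @classmethod
    def from_text(cls, path) -> "EventStream":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError("missing event-stream header line")
            meta = dict(kv.split("=") for kv in header[1:].split())
            rows = [line.strip().split(",") for line in fh if line.strip()]
        t = np.array([float(r[0]) for r in rows])
        x = np.array([int(r[1]) for r in rows])
        y = np.array([int(r[2]) for r in rows])
        p = np.array([int(r[3]) for r in rows])
        return cls(t, x, y, p, int(meta["width"]), int(meta["height"]),
                   float(meta["duration"]))


def poisson_spike_train(rates, T: int, dt: float = 1.0, seed=None) -> np.ndarray:
    """Binary spike tensor (T, n_units) of independent Poisson trains.

    Poisson firing is approximated per bin as Bernoulli(rate * dt / 1000),
    standard at millisecond bins.  ``rates`` are per-unit rates in Hz (a scalar
    is broadcast).  Requires rate*dt <= 1000 so the probability is <= 1.
    """
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    if np.any(rates < 0):
        raise ValueError("rates must be >= 0")
    prob = rates * dt / 1000.0
    if np.any(prob > 1.0):
        raise ValueError("rate * dt exceeds 1000 Hz*ms (spike probability > 1)")
    rng = np.random.default_rng(seed)
    return (rng.random((T, rates.size)) < prob).astype(float)


def regression_targets(T: int, dt: float = 1.0, f_hi: float = 20.0,
                       f_lo: float = 2.0) -> np.ndarray:
    """Three pseudo-target traces, shape (T, 3), all in [0, 1].

    Column 0 is a linear ramp from 0 to 1 over the duration; columns 1 and 2
    are high- and low-frequency sinusoids (1 + sin(2 pi f t)) / 2.  Defaults
    f_hi = 20 Hz and f_lo = 2 Hz resolve one fast and one slow component
    within a 500 ms window.
    """
    if T < 2:
        raise ValueError("need at least 2 timesteps")
    t = np.arange(T) * dt / 1000.0  # seconds
    ramp = np.linspace(0.0, 1.0, T)
    hi = 0.5 * (1.0 + np.sin(2.0 * np.pi * f_hi * t))
    lo = 0.5 * (1.0 + np.sin(2.0 * np.pi * f_lo * t))
    return np.stack([ramp, hi, lo], axis=1)


def _bar_sweep(n_steps: int, span: int, speed: float, bar_width: int):
    """Leading/trailing edge positions of a periodic bar sweep (direction +1),
    wrapping within ``span`` pixels measured from the entry side."""
    pos = (np.arange(n_steps) * speed).astype(int)
    lead = (pos + bar_width) % span
    trail = pos % span
    return lead, trail


def moving_bar_events(
    class_id: int,
    width: int = 16,
    height: int = 16,
    duration: float = 300.0,
    dt: float = 1.0,
    speed: float = 1.0,
    bar_width: int = 2,
    jitter: float = 0.25,
    noise_rate: float = 1.0,
    sweep_fraction: float = 0.5,
    seed=None,
) -> EventStream:
    """DVS-like event stream of a bright bar sweeping across the sensor.

    The class catalog selects the sweep axis and direction (see
    :data:`MOVING_BAR_CLASSES`).  At each step the bar advances ``speed``
    pixels, wrapping periodically within its sweep region — the
    ``sweep_fraction`` of the sensor adjacent to the side it enters from, so
    different classes occupy different pixels on average and the binned
    per-class means are linearly separable at the pixel level.  Every pixel
    of the newly-covered edge emits an ON event while the just-vacated edge
    emits an OFF event: leading and trailing edges co-occur with opposite
    polarities, as with a real change-detecting sensor.  Timestamp jitter
    (uniform, +-``jitter`` ms) and uniform salt-and-pepper noise events
    (``noise_rate`` Hz per pixel per polarity) are added on top.
    Deterministic given the seed.

    The sweep for a negative direction is the positive-direction sweep with
    the coordinate mirrored and polarities swapped, so mirror symmetry holds
    exactly at zero jitter and noise.
    """
    if class_id not in MOVING_BAR_CLASSES:
        raise ValueError(f"unknown class id {class_id}; catalog has {sorted(MOVING_BAR_CLASSES)}")
    axis, direction = MOVING_BAR_CLASSES[class_id]
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    size = width if axis == "x" else height
    extent = height if axis == "x" else width  # pixels along the bar
    span = max(int(round(size * sweep_fraction)), bar_width + 1)

    lead, trail = _bar_sweep(n_steps, span, speed, bar_width)
    steps = np.repeat(np.arange(n_steps), 2 * extent)
    along = np.tile(np.concatenate([np.arange(extent), np.arange(extent)]), n_steps)
    sweep_coord = np.repeat(np.stack([lead, trail], axis=1).reshape(-1), extent)
    pol = np.tile(np.concatenate([np.full(extent, ON), np.full(extent, OFF)]), n_steps)

    if direction < 0:
        sweep_coord = size - 1 - sweep_coord
        pol = 1 - pol
    if axis == "x":
        x, y = sweep_coord, along
    else:
        x, y = along, sweep_coord

    t = steps * dt
    if jitter > 0:
        t = t + rng.uniform(-jitter, jitter, size=t.shape)
    t = np.clip(t, 0.0, np.nextafter(duration, 0.0))

    n_noise = rng.poisson(noise_rate * width * height * 2 * duration / 1000.0)
    if n_noise:
        t = np.concatenate([t, rng.uniform(0.0, duration, n_noise)])
        x = np.concatenate([x, rng.integers(0, width, n_noise)])
        y = np.concatenate([y, rng.integers(0, height, n_noise)])
        pol = np.concatenate([pol, rng.integers(0, 2, n_noise)])

    stream = EventStream(t.astype(float), np.asarray(x, dtype=int),
                         np.asarray(y, dtype=int), np.asarray(pol, dtype=int),
                         width, height, duration)
    return stream.sort()


def bin_events(stream: EventStream, bin_ms: float = 1.0,
               spatial_factor: int = 1) -> np.ndarray:
    """Dense frame tensor (n_bins, 2, H', W') of event counts.

    Events are summed into ``bin_ms`` time bins per polarity channel;
    ``spatial_factor`` f sums f x f pixel neighbourhoods (f = 2 merges four
    neighbouring pixels).  The total count is conserved: the tensor sums to
    the number of events.
    """
    if bin_ms <= 0:
        raise ValueError("bin width must be positive")
    if stream.width % spatial_factor or stream.height % spatial_factor:
        raise ValueError(
            f"sensor {stream.height}x{stream.width} not divisible by factor {spatial_factor}")
    n_bins = int(np.ceil(stream.duration / bin_ms))
    H, W = stream.height // spatial_factor, stream.width // spatial_factor
    frames = np.zeros((n_bins, 2, H, W), dtype=np.int64)
    if len(stream):
        b = np.minimum((stream.t / bin_ms).astype(int), n_bins - 1)
        np.add.at(frames, (b, stream.p, stream.y // spatial_factor,
                           stream.x // spatial_factor), 1)
    return frames


def slice_sequence(frames: np.ndarray, slice_len: int, seed=None) -> np.ndarray:
    """Random contiguous slice of ``slice_len`` bins along the time axis.

    The start is uniform over all valid positions (inclusive of both ends), so
    a full-length slice is possible from either boundary.
    """
    T = frames.shape[0]
    if slice_len > T:
        raise ValueError(f"slice of {slice_len} bins from only {T}")
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, T - slice_len + 1))
    return frames[start:start + slice_len]
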