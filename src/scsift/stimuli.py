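"""Stimulus movies and trial protocols.

Stimuli are described in visual degrees and Weber contrast relative to a
uniform gray background: 0 is gray, -1 full black, +1 full white.  A
:class:`StimulusMovie` holds the space-time contrast field ``s(x, y, t)``
sampled on a pixel grid (default 1 deg/sample) at the monitor refresh
rate (default 60 Hz).  Disks are rasterized without anti-aliasing: a
pixel belongs to a disk iff its center lies within the disk radius,
which keeps pixel counts exactly reproducible.

Protocols are ordered, temporally disjoint lists of
:class:`TrialEvent`.  Movies are always rendered on demand from event
parameters (checkerboards from their seed), never stored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

DEFAULT_PIXEL_PITCH = 1.0  # deg / sample
DEFAULT_FRAME_RATE = 60.0  # Hz, monitor refresh

#: Looming defaults: disk expands 0 -> 30 deg diameter at 60 deg/s of
#: diameter growth, then holds for 250 ms before disappearing.
LOOM_FINAL_DIAMETER = 30.0
LOOM_SPEED = 60.0
LOOM_HOLD = 0.25

#: Inter-stimulus intervals of the habituation-recovery sequence, in
#: order.  Eight looms separated by these seven gaps.
RECOVERY_ISIS = (1.5, 2.0, 6.0, 11.0, 21.0, 61.0, 121.0)

STIMULUS_KINDS = (
    "loom_dark",
    "contract_dark",
    "expand_white",
    "contract_white",
    "dimming",
    "moving_dark",
    "checkerboard",
)


@dataclass
class StimulusMovie:
    """Space-time Weber-contrast field.

    ``values`` has shape ``(n_frames, ny, nx)``; pixel ``(j, i)`` covers
    the half-open square with lower-left corner
    ``(origin[0] + i * pixel_pitch, origin[1] + j * pixel_pitch)``.
    Frame ``k`` shows the stimulus state at time ``k / frame_rate``.
    """

    values: np.ndarray
    pixel_pitch: float = DEFAULT_PIXEL_PITCH
    frame_rate: float = DEFAULT_FRAME_RATE
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.shape[0] < 1:
            raise ValueError("movie must be (n_frames, ny, nx) with >= 1 frame")
        if self.frame_rate <= 0 or self.pixel_pitch <= 0:
            raise ValueError("frame_rate and pixel_pitch must be positive")
        vmax = float(np.max(np.abs(self.values))) if self.values.size else 0.0
        if vmax > 1.0 + 1e-9:
            raise ValueError("contrast values must lie in [-1, +1]")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) coordinates (deg) of pixel centers.

        x has length nx, y has length ny.
        """
        ny, nx = self.values.shape[1:]
        x = self.origin[0] + (np.arange(nx) + 0.5) * self.pixel_pitch
        y = self.origin[1] + (np.arange(ny) + 0.5) * self.pixel_pitch
        return x, y


@dataclass
class TrialEvent:
    """One stimulus presentation: kind, location, onset and duration."""

    kind: str
    center: tuple[float, float]
    onset: float
    duration: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in STIMULUS_KINDS:
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")

    @property
    def end(self) -> float:
        return self.onset + self.duration

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "center": list(self.center),
            "onset": self.onset,
            "duration": self.duration,
            "params": dict(self.params),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrialEvent":
        return cls(
            kind=d["kind"],
            center=tuple(d["center"]),
            onset=float(d["onset"]),
            duration=float(d["duration"]),
            params=dict(d.get("params", {})),
        )


@dataclass
class Protocol:
    """Ordered, temporally disjoint stimulus presentations.

    ``duration`` is the nominal recording length (seconds); it includes
    the inter-stimulus gray period following the last event where the
    generating protocol defines one.
    """

    events: list[TrialEvent]
    duration: float
    grid: np.ndarray | None = None  # (n_locations, 2) loom grid, if any
    seed: int | None = None
    screen_bounds: tuple[tuple[float, float], tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.grid is not None:
            self.grid = np.asarray(self.grid, dtype=float)
        prev_end = -np.inf
        for k, ev in enumerate(self.events):
            if ev.onset < prev_end - 1e-9:
                raise ValueError(f"event {k} overlaps the previous event")
            prev_end = ev.end
        if self.events and self.duration < self.events[-1].end - 1e-9:
            raise ValueError("protocol duration shorter than its last event")
        if self.screen_bounds is not None:
            (x0, x1), (y0, y1) = self.screen_bounds
            for k, ev in enumerate(self.events):
                cx, cy = ev.center
                if not (x0 <= cx <= x1 and y0 <= cy <= y1):
                    raise ValueError(
                        f"event {k} center {ev.center} outside screen bounds"
                    )

    @property
    def n_events(self) -> int:
        return len(self.events)

    def to_json(self) -> str:
        payload = {
            "duration": self.duration,
            "seed": self.seed,
            "grid": None if self.grid is None else self.grid.tolist(),
            "screen_bounds": self.screen_bounds,
            "events": [ev.to_dict() for ev in self.events],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Protocol":
        d = json.loads(text)
        sb = d.get("screen_bounds")
        if sb is not None:
            sb = (tuple(sb[0]), tuple(sb[1]))
        return cls(
            events=[TrialEvent.from_dict(e) for e in d["events"]],
            duration=float(d["duration"]),
            grid=None if d.get("grid") is None else np.asarray(d["grid"]),
            seed=d.get("seed"),
            screen_bounds=sb,
        )


# ---------------------------------------------------------------------------
# movie builders
# ---------------------------------------------------------------------------


def _movie_grid(
    bounds: tuple[tuple[float, float], tuple[float, float]],
    pixel_pitch: float,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Pixel-center coordinates covering ``bounds`` at ``pixel_pitch``."""
    (x0, x1), (y0, y1) = bounds
    nx = max(1, int(np.ceil((x1 - x0) / pixel_pitch - 1e-9)))
    ny = max(1, int(np.ceil((y1 - y0) / pixel_pitch - 1e-9)))
    x = x0 + (np.arange(nx) + 0.5) * pixel_pitch
    y = y0 + (np.arange(ny) + 0.5) * pixel_pitch
    return x, y, (x0, y0)


def _default_disk_bounds(
    center: tuple[float, float], max_radius: float, pixel_pitch: float
) -> tuple[tuple[float, float], tuple[float, float]]:
    pad = max_radius + 2.0 * pixel_pitch
    return (
        (center[0] - pad, center[0] + pad),
        (center[1] - pad, center[1] + pad),
    )


def _disk_movie(
    center: tuple[float, float],
    radii: np.ndarray,
    contrasts: np.ndarray,
    disk_centers: np.ndarray,
    pixel_pitch: float,
    frame_rate: float,
    bounds: tuple[tuple[float, float], tuple[float, float]] | None,
) -> StimulusMovie:
    """Rasterize a (possibly moving, growing, dimming) disk."""
    max_r = float(np.max(radii))
    if bounds is None:
        span = np.ptp(disk_centers, axis=0)
        mid = (disk_centers.min(axis=0) + disk_centers.max(axis=0)) / 2.0
        pad = max_r + 2.0 * pixel_pitch
        bounds = (
            (mid[0] - span[0] / 2 - pad, mid[0] + span[0] / 2 + pad),
            (mid[1] - span[1] / 2 - pad, mid[1] + span[1] / 2 + pad),
        )
    else:
        (bx0, bx1), (by0, by1) = bounds
        for k, (r, (cx, cy)) in enumerate(zip(radii, disk_centers)):
            if r > 0 and (
                cx - r < bx0 - 1e-9
                or cx + r > bx1 + 1e-9
                or cy - r < by0 - 1e-9
                or cy + r > by1 + 1e-9
            ):
                raise ValueError(
                    f"disk exceeds screen bounds at frame {k} "
                    f"(center {(cx, cy)}, radius {r:.2f} deg)"
                )
    x, y, origin = _movie_grid(bounds, pixel_pitch)
    n_frames = len(radii)
    values = np.zeros((n_frames, len(y), len(x)), dtype=np.float64)
    xx, yy = np.meshgrid(x, y)
    for k in range(n_frames):
        if radii[k] <= 0 or contrasts[k] == 0:
            continue
        cx, cy = disk_centers[k]
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radii[k] ** 2
        values[k][mask] = contrasts[k]
    return StimulusMovie(values, pixel_pitch, frame_rate, origin)


def _n_frames(duration: float, frame_rate: float) -> int:
    n = int(round(duration * frame_rate))
    if n < 1:
        raise ValueError("stimulus shorter than one frame")
    return n


def loom_movie(
    center: tuple[float, float],
    final_diameter: float = LOOM_FINAL_DIAMETER,
    speed: float = LOOM_SPEED,
    hold: float = LOOM_HOLD,
    contrast: float = -1.0,
    pixel_pitch: float = DEFAULT_PIXEL_PITCH,
    frame_rate: float = DEFAULT_FRAME_RATE,
    bounds: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> StimulusMovie:
    """Expanding disk: diameter grows linearly from 0 at ``speed``
    (deg/s), holds at ``final_diameter`` for ``hold`` seconds, then the
    field returns to gray.  Total duration final_diameter/speed + hold.
    """
    if final_diameter <= 0:
        raise ValueError("final_diameter must be > 0")
    if speed <= 0:
        raise ValueError("speed must be > 0")
    duration = final_diameter / speed + hold
    n = _n_frames(duration, frame_rate)
    t = np.arange(n) / frame_rate
    radii = np.minimum(speed * t, final_diameter) / 2.0
    centers = np.tile(np.asarray(center, dtype=float), (n, 1))
    contrasts = np.full(n, contrast)
    if bounds is None:
        bounds = _default_disk_bounds(center, final_diameter / 2.0, pixel_pitch)
    return _disk_movie(center, radii, contrasts, centers, pixel_pitch, frame_rate, bounds)


def figural_movie(
    kind: str,
    center: tuple[float, float],
    final_diameter: float = LOOM_FINAL_DIAMETER,
    speed: float = LOOM_SPEED,
    hold: float = LOOM_HOLD,
    pixel_pitch: float = DEFAULT_PIXEL_PITCH,
    frame_rate: float = DEFAULT_FRAME_RATE,
    bounds: tuple[tuple[float, float], tuple[float, float]] | None = None,
    direction: tuple[float, float] = (1.0, 0.0),
    path_length: float | None = None,
    final_contrast: float = -1.0,
) -> StimulusMovie:
    """Figural control stimuli sharing the looming geometry.

    - ``expand_white``: as the loom but full white.
    - ``contract_dark`` / ``contract_white``: disk shrinks from the
      final looming diameter to 0, with the 250 ms stationary period at
      the end (i.e. gray).
    - ``dimming``: disk of fixed ``final_diameter`` whose contrast
      ramps linearly from 0 to ``final_contrast`` over the looming
      duration.
    - ``moving_dark``: dark disk of ``final_diameter`` translating at
      ``speed`` along ``direction`` with ``center`` at the middle of
      the trajectory.
    """
    if kind in ("loom_dark", "checkerboard"):
        raise ValueError(f"{kind!r} is not a figural stimulus")
    if kind not in STIMULUS_KINDS:
        raise ValueError(f"unknown stimulus kind {kind!r}")

    if kind == "expand_white":
        return loom_movie(
            center, final_diameter, speed, hold, +1.0, pixel_pitch, frame_rate, bounds
        )

    if kind in ("contract_dark", "contract_white"):
        duration = final_diameter / speed + hold
        n = _n_frames(duration, frame_rate)
        t = np.arange(n) / frame_rate
        radii = np.maximum(final_diameter - speed * t, 0.0) / 2.0
        centers = np.tile(np.asarray(center, dtype=float), (n, 1))
        contrast = -1.0 if kind == "contract_dark" else +1.0
        contrasts = np.full(n, contrast)
        if bounds is None:
            bounds = _default_disk_bounds(center, final_diameter / 2.0, pixel_pitch)
        return _disk_movie(
            center, radii, contrasts, centers, pixel_pitch, frame_rate, bounds
        )

    if kind == "dimming":
        duration = final_diameter / speed + hold
        n = _n_frames(duration, frame_rate)
        t = np.arange(n) / frame_rate
        radii = np.full(n, final_diameter / 2.0)
        contrasts = final_contrast * t / duration
        centers = np.tile(np.asarray(center, dtype=float), (n, 1))
        if bounds is None:
            bounds = _default_disk_bounds(center, final_diameter / 2.0, pixel_pitch)
        return _disk_movie(
            center, radii, contrasts, centers, pixel_pitch, frame_rate, bounds
        )

    # moving_dark
    if path_length is None:
        # match the duration of the default loom
        path_length = speed * (final_diameter / LOOM_SPEED + hold)
    duration = path_length / speed
    n = _n_frames(duration, frame_rate)
    t = np.arange(n) / frame_rate
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    offsets = (speed * t - path_length / 2.0)[:, None] * d[None, :]
    centers = np.asarray(center, dtype=float)[None, :] + offsets
    radii = np.full(n, final_diameter / 2.0)
    contrasts = np.full(n, -1.0)
    return _disk_movie(center, radii, contrasts, centers, pixel_pitch, frame_rate, bounds)


def checkerboard_movie(
    duration: float,
    checker: float = 3.0,
    rate: float = DEFAULT_FRAME_RATE,
    seed: int = 0,
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((-15.0, 15.0), (-15.0, 15.0)),
    pixel_pitch: float = DEFAULT_PIXEL_PITCH,
) -> StimulusMovie:
    """Flickering binary checkerboard: square checkers whose contrast is
    drawn independently from {-1, +1} on every frame.  Deterministic
    given ``seed``.
    """
    if checker < pixel_pitch:
        raise ValueError("checker size must be >= pixel pitch")
    n = _n_frames(duration, rate)
    x, y, origin = _movie_grid(bounds, pixel_pitch)
    nx, ny = len(x), len(y)
    ncx = int(np.ceil(nx * pixel_pitch / checker))
    ncy = int(np.ceil(ny * pixel_pitch / checker))
    rng = np.random.default_rng(seed)
    checks = rng.integers(0, 2, size=(n, ncy, ncx), dtype=np.int8) * 2 - 1
    reps = int(round(checker / pixel_pitch))
    values = np.repeat(np.repeat(checks, reps, axis=1), reps, axis=2)
    values = values[:, :ny, :nx].astype(np.float32)
    return StimulusMovie(values, pixel_pitch, rate, origin)


def render_event(
    event: TrialEvent,
    pixel_pitch: float = DEFAULT_PIXEL_PITCH,
    frame_rate: float = DEFAULT_FRAME_RATE,
    bounds: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> StimulusMovie:
    """Render one protocol event to a movie (on its own spatial grid)."""
    p = dict(event.params)
    if event.kind == "loom_dark":
        return loom_movie(
            event.center,
            final_diameter=p.get("final_diameter", LOOM_FINAL_DIAMETER),
            speed=p.get("speed", LOOM_SPEED),
            hold=p.get("hold", LOOM_HOLD),
            contrast=p.get("contrast", -1.0),
            pixel_pitch=pixel_pitch,
            frame_rate=frame_rate,
            bounds=bounds,
        )
    if event.kind == "checkerboard":
        return checkerboard_movie(
            event.duration,
            checker=p.get("checker", 3.0),
            rate=frame_rate,
            seed=p.get("seed", 0),
            bounds=bounds if bounds is not None else p.get("bounds", ((-15, 15), (-15, 15))),
            pixel_pitch=pixel_pitch,
        )
    return figural_movie(
        event.kind,
        event.center,
        final_diameter=p.get("final_diameter", LOOM_FINAL_DIAMETER),
        speed=p.get("speed", LOOM_SPEED),
        hold=p.get("hold", LOOM_HOLD),
        pixel_pitch=pixel_pitch,
        frame_rate=frame_rate,
        bounds=bounds,
        direction=p.get("direction", (1.0, 0.0)),
        path_length=p.get("path_length"),
        final_contrast=p.get("final_contrast", -1.0),
    )


def render_protocol(
    protocol: Protocol,
    bounds: tuple[tuple[float, float], tuple[float, float]],
    pixel_pitch: float = DEFAULT_PIXEL_PITCH,
    frame_rate: float = DEFAULT_FRAME_RATE,
) -> StimulusMovie:
    """Render a whole protocol on a common grid (gray between events).

    Intended for small protocols; large experiments are simulated
    event-by-event instead.
    """
    x, y, origin = _movie_grid(bounds, pixel_pitch)
    n = _n_frames(protocol.duration, frame_rate)
    values = np.zeros((n, len(y), len(x)))
    for ev in protocol.events:
        sub = render_event(ev, pixel_pitch, frame_rate, bounds=bounds)
        k0 = int(round(ev.onset * frame_rate))
        k1 = min(n, k0 + sub.n_frames)
        values[k0:k1] = sub.values[: k1 - k0]
    return StimulusMovie(values, pixel_pitch, frame_rate, origin)


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------


def grid_locations(
    shape: tuple[int, int] = (5, 5),
    spacing: float = 15.0,
    center: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Centers of a rows x cols stimulus grid, row-major from the
    bottom-left, as an (n, 2) array of (x, y) degrees."""
    rows, cols = shape
    xs = (np.arange(cols) - (cols - 1) / 2.0) * spacing + center[0]
    ys = (np.arange(rows) - (rows - 1) / 2.0) * spacing + center[1]
    pts = [(x, y) for y in ys for x in xs]
    return np.asarray(pts, dtype=float)


def _loom_event(location, onset, final_diameter, speed, hold) -> TrialEvent:
    duration = final_diameter / speed + hold
    return TrialEvent(
        kind="loom_dark",
        center=tuple(location),
        onset=onset,
        duration=duration,
        params={"final_diameter": final_diameter, "speed": speed, "hold": hold},
    )


def repeat_loom_protocol(
    n_trials: int,
    isi: float,
    location: tuple[float, float] = (0.0, 0.0),
    final_diameter: float = LOOM_FINAL_DIAMETER,
    speed: float = LOOM_SPEED,
    hold: float = LOOM_HOLD,
) -> Protocol:
    """Identical looms repeated at one location with a fixed ISI."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if isi <= 0:
        raise ValueError("isi must be > 0")
    duration = final_diameter / speed + hold
    events = [
        _loom_event(location, k * (duration + isi), final_diameter, speed, hold)
        for k in range(n_trials)
    ]
    return Protocol(events=events, duration=n_trials * (duration + isi))


def random_loom_protocol(
    n_trials: int = 100,
    isi: float = 3.0,
    grid_shape: tuple[int, int] = (5, 5),
    spacing: float = 15.0,
    center: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    final_diameter: float = LOOM_FINAL_DIAMETER,
    speed: float = LOOM_SPEED,
    hold: float = LOOM_HOLD,
    screen_bounds: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> Protocol:
    """Looming stimuli at locations drawn uniformly and independently
    from a 5 x 5 grid with 15 deg spacing (the "random loom" design)."""
    grid = grid_locations(grid_shape, spacing, center)
    if screen_bounds is not None:
        (x0, x1), (y0, y1) = screen_bounds
        if not (
            grid[:, 0].min() >= x0
            and grid[:, 0].max() <= x1
            and grid[:, 1].min() >= y0
            and grid[:, 1].max() <= y1
        ):
            raise ValueError("stimulus grid does not fit within screen bounds")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(grid), size=n_trials)
    duration = final_diameter / speed + hold
    events = [
        _loom_event(grid[i], k * (duration + isi), final_diameter, speed, hold)
        for k, i in enumerate(idx)
    ]
    return Protocol(
        events=events,
        duration=n_trials * (duration + isi),
        grid=grid,
        seed=seed,
        screen_bounds=screen_bounds,
    )


def recovery_protocol(
    location: tuple[float, float] = (0.0, 0.0),
    isis: Sequence[float] = RECOVERY_ISIS,
    final_diameter: float = LOOM_FINAL_DIAMETER,
    speed: float = LOOM_SPEED,
    hold: float = LOOM_HOLD,
) -> Protocol:
    """Loom series probing recovery from habituation: one initial loom
    followed by looms after each listed inter-stimulus interval."""
    duration = final_diameter / speed + hold
    onset = 0.0
    events = [_loom_event(location, onset, final_diameter, speed, hold)]
    for isi in isis:
        onset += duration + isi
        events.append(_loom_event(location, onset, final_diameter, speed, hold))
    return Protocol(events=events, duration=onset + duration + 1.0)
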