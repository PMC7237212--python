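"""LN-cascade circuit model of looming selectivity, position invariance
and stimulus-specific habituation.

The working model chains three stages:

1. *LN input units.*  Each unit computes a drive
   ``g(t) = s(x,y,t) * k(x,y,t)`` — the space-time convolution of the
   stimulus with a separable kernel ``k = F(x,y) T(t)`` — followed by a
   half-wave rectifier ``N(g) = max(0, m g - theta)``.  The spatial
   kernel is an isotropic Gaussian; the temporal kernel is a biphasic
   difference of gamma-like lobes

   ``T(t) = (t/tau1)^n1 exp(-n1 (t/tau1 - 1))
          - b (t/tau2)^n2 exp(-n2 (t/tau2 - 1))``.

   Both inputs are Off-type.  The polarity lives in the temporal
   kernel itself: with the tabulated parameters the leading lobe of
   ``T`` is negative (the shape of an Off cell's spike-triggered
   average read as a causal filter), so a luminance *decrement*
   produces a positive transient drive without any extra sign flip.

2. *Local looming detectors.*  A small fast center unit and a
   concentric wide slow surround unit are combined as
   ``r_LD(t) = N(r_c(t) - r_s(t))``: the detector fires only while the
   center outruns the surround, which happens for an expanding dark
   edge but not for dimming, receding or translating stimuli.

3. *Widefield pooling with synaptic depression.*  Detectors tile the
   field on a 15-deg grid and converge onto one widefield unit,
   ``r_WF(t) = sum_i w_i r_LD,i(t)``.  Each synaptic weight obeys
   ``dw/dt = (1 - w)/tau - a (w - w_min) r(t)``: presynaptic firing
   depresses the weight toward ``w_min`` with gain ``a``, and it
   recovers toward 1 with time constant ``tau``.  Depression of one
   synapse leaves the others untouched, which makes the habituation
   specific to the stimulated grid location.

The spatial Gaussians of center and surround are normalized to unit
L2 norm, giving the surround an effective gain of sigma_s / sigma_c
relative to the center.  This convention is what makes the detector
mechanism work: with unit-peak Gaussians the wide surround collects
~(sigma_s/sigma_c)^2 times the center's input and vetoes every
stimulus including the loom, while with unit-volume Gaussians the
surround is too weak to veto receding, translating or remote stimuli.
Energy normalization sits between the two and yields a detector that
responds to a centered expanding dark disk with short latency and
rejects dimming, translating and off-center stimuli.

Detector rates are dimensionless.  They are normalized so that the
time-integrated response of a centered detector to the standard loom
(30 deg final diameter at 60 deg/s, 250 ms hold) equals
``loom_response_integral`` (default 4).  With depression gain a = 1
this integral acts as the per-trial "depression dose": one centered
loom multiplies the local weight by roughly exp(-4), i.e. habituation
is nearly complete after a single presentation while synapses of
silent detectors are untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace


import numpy as np
from scipy.signal import fftconvolve

from .stimuli import (
    DEFAULT_FRAME_RATE,
    DEFAULT_PIXEL_PITCH,
    LOOM_FINAL_DIAMETER,
    LOOM_HOLD,
    LOOM_SPEED,
    Protocol,
    StimulusMovie,
    grid_locations,
    loom_movie,
    render_event,
)

# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TemporalKernelParams:
    """Biphasic temporal kernel parameters (times in seconds)."""

    tau1: float
    n1: float
    tau2: float
    n2: float
    b: float

    def __post_init__(self) -> None:
        if self.tau1 <= 0 or self.tau2 <= 0 or self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("tau1, tau2, n1, n2 must be positive")


@dataclass(frozen=True)
class SpatialKernelParams:
    """Isotropic Gaussian spatial kernel, sigma in degrees."""

    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class Rectifier:
    """Half-wave rectifier N(g) = max(0, m g - theta)."""

    m: float = 1.0
    theta: float = 0.0

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError("gain m must be >= 0")

    def __call__(self, g: np.ndarray) -> np.ndarray:
        return np.maximum(0.0, self.m * np.asarray(g) - self.theta)


#: Temporal kernels fitted to mouse alpha retinal ganglion cells; the
#: fast transient kernel forms the detector center, the slower one the
#: surround.
CENTER_TEMPORAL = TemporalKernelParams(tau1=0.104, n1=2.77, tau2=0.0912, n2=3.94, b=1.34)
SURROUND_TEMPORAL = TemporalKernelParams(tau1=0.0846, n1=1.24, tau2=0.0797, n2=1.87, b=1.33)
CENTER_SIGMA = 4.0  # deg
SURROUND_SIGMA = 10.0  # deg


def eval_temporal_kernel(params: TemporalKernelParams, t) -> np.ndarray:
    """Evaluate T(t); causal, so 0 for t < 0."""
    t = np.asarray(t, dtype=float)
    pos = np.maximum(t, 0.0)
    with np.errstate(invalid="ignore"):
        lobe1 = (pos / params.tau1) ** params.n1 * np.exp(
            -params.n1 * (pos / params.tau1 - 1.0)
        )
        lobe2 = (pos / params.tau2) ** params.n2 * np.exp(
            -params.n2 * (pos / params.tau2 - 1.0)
        )
    out = np.where(t < 0, 0.0, lobe1 - params.b * lobe2)
    return out if out.ndim else float(out)


def spatial_amplitude(sigma: float) -> float:
    """Amplitude normalizing the 2-D Gaussian F to unit L2 norm:
    integral of (A F)^2 over the plane equals 1."""
    return 1.0 / (sigma * np.sqrt(np.pi))


def eval_spatial_kernel(params: SpatialKernelParams, x, y) -> np.ndarray:
    """Evaluate F(x, y) = exp(-(x^2 + y^2) / (2 sigma^2)), coordinates
    relative to the unit center."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = np.exp(-(x**2 + y**2) / (2.0 * params.sigma**2))
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# LN units and looming detectors
# ---------------------------------------------------------------------------


@dataclass
class RateTrace:
    """Nonnegative firing rate sampled at fixed dt; the linear drive
    g(t) (which can be negative) is kept when requested."""

    values: np.ndarray
    dt: float
    drive: np.ndarray | None = None

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.dt

    def integral(self) -> float:
        return float(np.sum(self.values) * self.dt)


@dataclass
class LNUnit:
    """Linear-nonlinear unit with a Gaussian spatial kernel, biphasic
    temporal kernel and half-wave output rectifier.  Off polarity:
    darkening at the center yields positive drive."""

    center: tuple[float, float]
    spatial: SpatialKernelParams
    temporal: TemporalKernelParams
    rectifier: Rectifier = field(default_factory=Rectifier)
    polarity: str = "off"

    def __post_init__(self) -> None:
        if self.polarity != "off":
            raise ValueError("only Off-type units are modeled")


@dataclass
class LoomingDetector:
    """Concentric fast-center / slow-surround pair; fires on the
    rectified difference of the two rates."""

    center_unit: LNUnit
    surround_unit: LNUnit
    rectifier: Rectifier = field(default_factory=Rectifier)

    def __post_init__(self) -> None:
        if tuple(self.center_unit.center) != tuple(self.surround_unit.center):
            raise ValueError("center and surround units must be concentric")

    @property
    def center(self) -> tuple[float, float]:
        return tuple(self.center_unit.center)


def make_detector(
    center: tuple[float, float],
    center_sigma: float = CENTER_SIGMA,
    surround_sigma: float = SURROUND_SIGMA,
    center_temporal: TemporalKernelParams = CENTER_TEMPORAL,
    surround_temporal: TemporalKernelParams = SURROUND_TEMPORAL,
) -> LoomingDetector:
    return LoomingDetector(
        center_unit=LNUnit(center, SpatialKernelParams(center_sigma), center_temporal),
        surround_unit=LNUnit(center, SpatialKernelParams(surround_sigma), surround_temporal),
    )


def temporal_kernel_samples(
    params: TemporalKernelParams, frame_rate: float, support: float = 0.5
) -> np.ndarray:
    """T(t) sampled at the frame grid over its truncated support."""
    n = max(2, int(round(support * frame_rate)))
    t = np.arange(n) / frame_rate
    return eval_temporal_kernel(params, t)


def spatial_projection(
    movie: StimulusMovie,
    centers: np.ndarray,
    sigma: float,
    sign: float = 1.0,
) -> np.ndarray:
    """Project each movie frame onto Gaussian fields at ``centers``.

    Returns an (n_units, n_frames) array
    ``sign * sum_xy A(sigma) F(x - cx, y - cy) s(x, y, t) pitch^2``.
    The Off polarity of the model units is carried by the temporal
    kernel, whose leading lobe is negative (as in the spike-triggered
    average of an Off cell), so the raw contrast enters with sign +1
    and a darkening still produces a positive transient drive.

    ``A(sigma) = 1 / (sigma sqrt(pi))`` normalizes each Gaussian to
    unit L2 norm, so a wide surround and a narrow center are matched in
    energy rather than in peak or in volume (see module docstring).
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    x, y = movie.pixel_centers()
    dx = x[None, :] - centers[:, 0:1]  # (U, nx)
    dy = y[None, :] - centers[:, 1:2]  # (U, ny)
    amp = spatial_amplitude(sigma)
    gx = amp * np.exp(-(dx**2) / (2.0 * sigma**2))
    gy = np.exp(-(dy**2) / (2.0 * sigma**2))
    # separable Gaussian: project over x then y for each unit
    vals = movie.values.astype(np.float64, copy=False)
    # (T, ny, nx) x (U, nx) -> (U, T, ny)
    px = np.einsum("tyx,ux->uty", vals, gx, optimize=True)
    proj = np.einsum("uty,uy->ut", px, gy, optimize=True)
    return sign * proj * movie.pixel_pitch**2


def _convolve_time(proj: np.ndarray, kernel: np.ndarray, dt: float, keep_tail: bool) -> np.ndarray:
    """Discrete causal temporal convolution along the last axis."""
    full = fftconvolve(proj, kernel[None, :], axes=-1) * dt
    if keep_tail:
        return full
    return full[..., : proj.shape[-1]]


def ln_response(
    movie: StimulusMovie,
    unit: LNUnit,
    keep_tail: bool = False,
    temporal_support: float = 0.5,
    return_drive: bool = False,
) -> RateTrace:
    """Rate of an LN unit driven by a movie.

    ``keep_tail`` extends the trace by the kernel support beyond the
    last stimulus frame (the response outlasts the stimulus).
    """
    if movie.pixel_pitch > unit.spatial.sigma / 2.0 + 1e-9:
        raise ValueError(
            "movie sampling too coarse for the spatial kernel "
            f"(pitch {movie.pixel_pitch} > sigma/2 = {unit.spatial.sigma / 2})"
        )
    proj = spatial_projection(movie, np.asarray([unit.center]), unit.spatial.sigma)
    kernel = temporal_kernel_samples(unit.temporal, movie.frame_rate, temporal_support)
    g = _convolve_time(proj, kernel, movie.dt, keep_tail)[0]
    r = unit.rectifier(g)
    return RateTrace(r, movie.dt, drive=g if return_drive else None)


def detector_response(
    det: LoomingDetector,
    movie: StimulusMovie,
    keep_tail: bool = False,
    temporal_support: float = 0.5,
) -> RateTrace:
    """Rectified center-minus-surround rate of one looming detector."""
    rc = ln_response(movie, det.center_unit, keep_tail, temporal_support)
    rs = ln_response(movie, det.surround_unit, keep_tail, temporal_support)
    if abs(rc.dt - rs.dt) > 1e-12:
        raise ValueError("center and surround traces have mismatched dt")
    return RateTrace(det.rectifier(rc.values - rs.values), rc.dt)


# ---------------------------------------------------------------------------
# depressing synapses
# ---------------------------------------------------------------------------


@dataclass
class DepressingSynapse:
    """Short-term depressing synapse with recovery.

    dw/dt = (1 - w)/tau_rec - a (w - w_min) r(t), w in [w_min, 1].
    """

    w: float = 1.0
    tau_rec: float = 180.0
    a: float = 1.0
    w_min: float = 0.0

    def __post_init__(self) -> None:
        if not (self.w_min <= self.w <= 1.0):
            raise ValueError("require w_min <= w <= 1")
        if self.tau_rec <= 0:
            raise ValueError("tau_rec must be positive")
        if self.a < 0:
            raise ValueError("a must be >= 0")


def depressed_weight_step(
    w: np.ndarray | float,
    r: np.ndarray | float,
    dt: float,
    tau_rec: float,
    a: float,
    w_min: float,
) -> np.ndarray | float:
    """Advance the synaptic weight ODE by one step of length ``dt``
    holding the presynaptic rate ``r`` constant.

    For frozen r the ODE is linear, dw/dt = A - B w with
    A = 1/tau + a w_min r and B = 1/tau + a r, so the update
    w <- w_inf + (w - w_inf) exp(-B dt) with w_inf = A/B is exact.
    This exponential integrator is unconditionally stable and keeps w
    inside [w_min, 1] for any step size.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    r = np.maximum(np.asarray(r, dtype=float), 0.0)
    B = 1.0 / tau_rec + a * r
    w_inf = (1.0 / tau_rec + a * w_min * r) / B
    out = w_inf + (np.asarray(w, dtype=float) - w_inf) * np.exp(-B * dt)
    out = np.clip(out, w_min, 1.0)
    return out if np.ndim(out) else float(out)


def synapse_step(syn: DepressingSynapse, r: float, dt: float) -> DepressingSynapse:
    """One integration step of the depression/recovery dynamics."""
    w = depressed_weight_step(syn.w, r, dt, syn.tau_rec, syn.a, syn.w_min)
    return replace(syn, w=float(w))


def synapse_steady_state(syn: DepressingSynapse, r: float) -> float:
    """Fixed point of the weight ODE under a constant rate r."""
    return (1.0 / syn.tau_rec + syn.a * syn.w_min * r) / (1.0 / syn.tau_rec + syn.a * r)


# ---------------------------------------------------------------------------
# widefield unit and full-circuit simulation
# ---------------------------------------------------------------------------


@dataclass
class WidefieldUnit:
    """Widefield neuron pooling a grid of looming detectors through
    matched depressing synapses."""

    detectors: list[LoomingDetector]
    synapses: list[DepressingSynapse]
    pooling_weights: np.ndarray | None = None  # fixed anatomical weights

    def __post_init__(self) -> None:
        if len(self.detectors) != len(self.synapses):
            raise ValueError("one synapse per detector required")
        if self.pooling_weights is None:
            self.pooling_weights = np.ones(len(self.detectors))
        self.pooling_weights = np.asarray(self.pooling_weights, dtype=float)

    @property
    def centers(self) -> np.ndarray:
        return np.asarray([d.center for d in self.detectors])


@dataclass
class WidefieldResponse:
    rate: RateTrace
    detector_rates: np.ndarray  # (n_detectors, n_frames)
    weights: np.ndarray  # (n_detectors, n_frames), value *before* each frame
    final_weights: np.ndarray


def _weight_pass(
    rates: np.ndarray,
    dt: float,
    w0: np.ndarray,
    pooling: np.ndarray,
    tau_rec: float,
    a: float,
    w_min: float,
    active: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sequential pass computing r_WF and the weight traces.

    At each frame the output uses the current weights, then every
    synapse is advanced with its own detector rate.  Frames with no
    detector activity are advanced in closed form (pure recovery),
    which keeps long gray gaps cheap.
    """
    n_det, n_frames = rates.shape
    weights = np.empty_like(rates)
    rwf = np.empty(n_frames)
    w = w0.copy()
    if active is None:
        active = rates.max(axis=0) > 0
    k = 0
    while k < n_frames:
        if active[k]:
            weights[:, k] = w
            rwf[k] = pooling @ (w * rates[:, k])
            w = depressed_weight_step(w, rates[:, k], dt, tau_rec, a, w_min)
            k += 1
        else:
            k2 = k
            while k2 < n_frames and not active[k2]:
                k2 += 1
            # closed-form recovery over the silent stretch
            span = np.arange(k2 - k)
            decay = np.exp(-span * dt / tau_rec)
            weights[:, k:k2] = 1.0 - (1.0 - w[:, None]) * decay[None, :]
            rwf[k:k2] = 0.0
            w = 1.0 - (1.0 - w) * np.exp(-(k2 - k) * dt / tau_rec)
            k = k2
    return rwf, weights


def widefield_response(
    wf: WidefieldUnit,
    movie: StimulusMovie,
    keep_tail: bool = False,
    rate_scale: float = 1.0,
) -> WidefieldResponse:
    """Drive a widefield unit with one movie, starting from the current
    synaptic weights (the unit itself is not mutated)."""
    rates = []
    for det in wf.detectors:
        rates.append(detector_response(det, movie, keep_tail=keep_tail).values)
    rates = np.asarray(rates) * rate_scale
    w0 = np.asarray([s.w for s in wf.synapses], dtype=float)
    syn = wf.synapses[0]
    rwf, weights = _weight_pass(
        rates, movie.dt, w0, wf.pooling_weights, syn.tau_rec, syn.a, syn.w_min
    )
    return WidefieldResponse(
        rate=RateTrace(rwf, movie.dt),
        detector_rates=rates,
        weights=weights,
        final_weights=weights[:, -1]
        if rates.shape[1]
        else w0,
    )


@dataclass
class CircuitConfig:
    """Full parameterization of the working model.

    ``tau_rec`` (synaptic recovery, seconds) is a free parameter of the
    depression model; the default 180 s keeps simulated recovery below
    50% of the naive response two minutes after habituation.
    ``loom_response_integral`` sets the dimensionless rate units (see
    module docstring).
    """

    grid_shape: tuple[int, int] = (5, 5)
    spacing: float = 15.0
    grid_center: tuple[float, float] = (0.0, 0.0)
    center_sigma: float = CENTER_SIGMA
    surround_sigma: float = SURROUND_SIGMA
    center_temporal: TemporalKernelParams = CENTER_TEMPORAL
    surround_temporal: TemporalKernelParams = SURROUND_TEMPORAL
    tau_rec: float = 180.0
    a: float = 1.0
    w_min: float = 0.0
    loom_response_integral: float = 4.0
    pixel_pitch: float = DEFAULT_PIXEL_PITCH
    frame_rate: float = DEFAULT_FRAME_RATE
    temporal_support: float = 0.5
    _rate_scale: float | None = field(default=None, repr=False, compare=False)

    def detector_centers(self) -> np.ndarray:
        return grid_locations(self.grid_shape, self.spacing, self.grid_center)

    def make_widefield(self) -> WidefieldUnit:
        centers = self.detector_centers()
        detectors = [
            make_detector(
                tuple(c),
                self.center_sigma,
                self.surround_sigma,
                self.center_temporal,
                self.surround_temporal,
            )
            for c in centers
        ]
        synapses = [
            DepressingSynapse(w=1.0, tau_rec=self.tau_rec, a=self.a, w_min=self.w_min)
            for _ in centers
        ]
        return WidefieldUnit(detectors, synapses)

    def detector_rates(self, movie: StimulusMovie, keep_tail: bool = True) -> np.ndarray:
        """Normalized rates of all grid detectors for one movie,
        vectorized across detectors: (n_detectors, n_frames)."""
        centers = self.detector_centers()
        proj_c = spatial_projection(movie, centers, self.center_sigma)
        proj_s = spatial_projection(movie, centers, self.surround_sigma)
        kc = temporal_kernel_samples(self.center_temporal, movie.frame_rate, self.temporal_support)
        ks = temporal_kernel_samples(self.surround_temporal, movie.frame_rate, self.temporal_support)
        rc = np.maximum(0.0, _convolve_time(proj_c, kc, movie.dt, keep_tail))
        rs = np.maximum(0.0, _convolve_time(proj_s, ks, movie.dt, keep_tail))
        n = min(rc.shape[1], rs.shape[1])
        return np.maximum(0.0, rc[:, :n] - rs[:, :n]) * self.rate_scale

    @property
    def rate_scale(self) -> float:
        """Normalization mapping raw convolution units to model rate
        units: the standard centered loom integrates to
        ``loom_response_integral``."""
        if self._rate_scale is None:
            det = make_detector(
                (0.0, 0.0),
                self.center_sigma,
                self.surround_sigma,
                self.center_temporal,
                self.surround_temporal,
            )
            movie = loom_movie(
                (0.0, 0.0),
                LOOM_FINAL_DIAMETER,
                LOOM_SPEED,
                LOOM_HOLD,
                pixel_pitch=self.pixel_pitch,
                frame_rate=self.frame_rate,
            )
            raw = detector_response(det, movie, keep_tail=True, temporal_support=self.temporal_support)
            integral = raw.integral()
            if integral <= 0:
                raise RuntimeError("standard loom produces no detector response")
            object.__setattr__(self, "_rate_scale", self.loom_response_integral / integral)
        return self._rate_scale


@dataclass
class SimulationResult:
    """Rates and synaptic-weight traces of a full protocol simulation,
    all sampled at ``dt`` from protocol time 0."""

    config: CircuitConfig
    protocol: Protocol
    detector_rates: np.ndarray  # (n_detectors, n_frames)
    weights: np.ndarray  # (n_detectors, n_frames)
    widefield: np.ndarray  # (n_frames,)
    dt: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.widefield.shape[0]) * self.dt

    @property
    def detector_centers(self) -> np.ndarray:
        return self.config.detector_centers()

    def event_integrals(self, pad: float = 0.0) -> np.ndarray:
        """Time-integrated widefield response per protocol event.

        By default the integral runs over the stimulus period only,
        matching the spike-count response definition of the analysis;
        ``pad`` extends the window past stimulus offset.
        """
        out = np.empty(len(self.protocol.events))
        n = len(self.widefield)
        for k, ev in enumerate(self.protocol.events):
            i0 = int(round(ev.onset / self.dt))
            i1 = min(n, int(round((ev.end + pad) / self.dt)))
            out[k] = np.sum(self.widefield[i0:i1]) * self.dt
        return out


def simulate_protocol(config: CircuitConfig, protocol: Protocol) -> SimulationResult:
    """Simulate the full circuit through a protocol.

    Events are rendered one at a time on their own spatial grid (the
    stimulus is zero elsewhere, so the convolutions are unaffected);
    detector responses are overlap-added onto the protocol timeline and
    the synaptic weights are advanced continuously through events and
    the gray gaps between them.
    """
    fr = config.frame_rate
    dt = 1.0 / fr
    tail = config.temporal_support
    n_frames = int(np.ceil((protocol.duration + tail) * fr))
    centers = config.detector_centers()
    n_det = len(centers)
    rates = np.zeros((n_det, n_frames))

    for k, ev in enumerate(protocol.events):
        if ev.kind != "checkerboard":
            d = np.linalg.norm(centers - np.asarray(ev.center), axis=1).min()
            if d > config.spacing / 2.0 + 1e-9:
                warnings.warn(
                    f"event {k} at {ev.center} lies outside the detector grid "
                    "coverage; simulating anyway",
                    stacklevel=2,
                )
        movie = render_event(ev, config.pixel_pitch, fr)
        ev_rates = config.detector_rates(movie, keep_tail=True)
        i0 = int(round(ev.onset * fr))
        i1 = min(n_frames, i0 + ev_rates.shape[1])
        rates[:, i0:i1] += ev_rates[:, : i1 - i0]

    w0 = np.ones(n_det)
    rwf, weights = _weight_pass(
        rates, dt, w0, np.ones(n_det), config.tau_rec, config.a, config.w_min
    )
    return SimulationResult(
        config=config,
        protocol=protocol,
        detector_rates=rates,
        weights=weights,
        widefield=rwf,
        dt=dt,
    )
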