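"""Spike-triggered average receptive fields and their space-time
separation.

Under white-noise stimulation (the flickering checkerboard) the mean
stimulus preceding spikes estimates a neuron's linear kernel.  The STA
here is a 3-D array over (lag, y, x): lag 0 is the frame containing
the spike, lag k the frame k steps earlier.  Singular value
decomposition of the (space x lag) unfolding expresses the STA as a
sum of rank-1 terms, each the product of a purely spatial map and a
purely temporal course; for center-surround neurons the first term
typically captures the center and the second the surround.

Sign convention: the SVD leaves each component's sign arbitrary, so
every temporal course is oriented to make its extremum nearest the
spike negative — the shape of an Off cell, which the large majority of
checkerboard-responsive collicular neurons are — and the spatial map
is flipped to compensate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimuli import StimulusMovie


@dataclass
class STA:
    """Spike-triggered average stimulus.

    ``values``: (n_lags, ny, nx), contrast units; lag axis runs
    backwards in time from the spike frame.
    """

    values: np.ndarray
    n_spikes: int
    lag_step: float  # s between consecutive lags (= 1 / frame rate)
    pixel_pitch: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    @property
    def n_lags(self) -> int:
        return self.values.shape[0]

    @property
    def lags_s(self) -> np.ndarray:
        return np.arange(self.n_lags) * self.lag_step


@dataclass
class STAComponent:
    spatial: np.ndarray  # (ny, nx), unit L2 norm
    temporal: np.ndarray  # (n_lags,), carries the amplitude
    singular_value: float
    variance_fraction: float


@dataclass
class STADecomposition:
    components: list[STAComponent]
    singular_values: np.ndarray  # all singular values, nonincreasing

    def reconstruction(self, rank: int | None = None) -> np.ndarray:
        """Sum of the first ``rank`` rank-1 terms, shaped like the STA."""
        comps = self.components if rank is None else self.components[:rank]
        ny, nx = comps[0].spatial.shape
        out = np.zeros((len(comps[0].temporal), ny, nx))
        for c in comps:
            out += c.temporal[:, None, None] * c.spatial[None, :, :]
        return out


def compute_sta(
    spike_times: np.ndarray,
    movie: StimulusMovie,
    n_lags: int = 30,
) -> STA:
    """Average the ``n_lags`` stimulus frames preceding each spike.

    A spike at time t is assigned to frame floor(t * frame_rate); each
    spike contributes one stimulus segment (spikes sharing a frame each
    count once).  Spikes earlier than the first full segment or outside
    the movie are dropped; at least one usable spike is required.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    frames = np.floor(spike_times * movie.frame_rate).astype(int)
    frames = frames[(frames >= n_lags - 1) & (frames < movie.n_frames)]
    if frames.size == 0:
        raise ValueError("no usable spikes after the first n_lags frames")
    vals = movie.values
    acc = np.zeros((n_lags,) + vals.shape[1:], dtype=np.float64)
    # chunked gather keeps memory bounded for long recordings
    for start in range(0, frames.size, 4096):
        f = frames[start : start + 4096]
        idx = f[:, None] - np.arange(n_lags)[None, :]  # (spikes, lags)
        acc += vals[idx].sum(axis=0)
    return STA(
        values=acc / frames.size,
        n_spikes=int(frames.size),
        lag_step=1.0 / movie.frame_rate,
        pixel_pitch=movie.pixel_pitch,
        origin=movie.origin,
    )


def svd_separate(sta: STA, n_components: int = 2) -> STADecomposition:
    """Split the STA into ranked space-time-separable components.

    The (n_lags, ny*nx) unfolding is decomposed as U S V^T; component
    k has temporal course U[:, k] * S[k] and spatial map V[k]
    (unit norm).  Variance fractions are S_k^2 / sum S^2.
    """
    n_lags, ny, nx = sta.values.shape
    m = sta.values.reshape(n_lags, ny * nx)
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    total = float((s**2).sum())
    comps = []
    for k in range(min(n_components, len(s))):
        temporal = u[:, k] * s[k]
        spatial = vt[k].reshape(ny, nx)
        # orient the near-spike temporal extremum negative (Off cells)
        peak = np.argmax(np.abs(temporal))
        if temporal[peak] > 0:
            temporal = -temporal
            spatial = -spatial
        comps.append(
            STAComponent(
                spatial=spatial,
                temporal=temporal,
                singular_value=float(s[k]),
                variance_fraction=float(s[k] ** 2 / total) if total > 0 else 0.0,
            )
        )
    return STADecomposition(components=comps, singular_values=s)


def spatial_peak(component: STAComponent, sta: STA) -> tuple[float, float]:
    """Location (deg) of the spatial map's absolute peak."""
    j, i = np.unravel_index(np.argmax(np.abs(component.spatial)), component.spatial.shape)
    x = sta.origin[0] + (i + 0.5) * sta.pixel_pitch
    y = sta.origin[1] + (j + 0.5) * sta.pixel_pitch
    return float(x), float(y)
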