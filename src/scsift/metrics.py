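"""Single-neuron spike-count statistics.

All analyses rest on one response definition: the *neural response* r'
is the number of spikes fired during the stimulus period, and the
*background activity* mu is the expected count contributed by the
baseline rate (estimated from the ~5 s just before the stimulus and
scaled to the stimulus duration).  Because many deep-SC neurons
habituate after a single presentation, responsiveness is judged on
single trials with a Poisson test rather than by repeat reliability:
r' is compared with Poisson(lambda), lambda = max(mu, 1) — the floor
keeps chance firing of 1-2 spikes from counting as a visual response —
and the response is significant when P(X >= r') < alpha (default
0.005), Bonferroni-corrected when many presentations are screened.

Derived quantities (with r = r' - mu, clamped at 0):

- selectivity index (r_L - r_O) / (r_L + r_O) between a looming
  response and another stimulus (or the checkerboard firing rate
  scaled to the loom duration),
- habituation index 1 - r_i / r_1 over repeated looms,
- recovery fraction r_i / r_1 over the increasing-ISI loom series,
- receptive-field size from the random-loom grid: 2x the
  response-weighted mean radial distance from the response center of
  mass, plus the grid spacing,
- latency variability: SD of the first spike time (>= 30 ms after
  onset) over significantly responsive trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_ALPHA = 0.005
LATENCY_MIN_S = 0.030


# ---------------------------------------------------------------------------
# background and significance
# ---------------------------------------------------------------------------


def background_activity(
    spike_times: np.ndarray,
    onset: float,
    duration: float,
    window: float = 5.0,
    recording_start: float = 0.0,
) -> tuple[float, bool]:
    """Expected stimulus-period count from the pre-stimulus baseline.

    Counts spikes in the ``window`` seconds before ``onset``, divides
    by the window length and multiplies by ``duration``.  Windows
    reaching before ``recording_start`` are truncated; returns
    ``(mu, truncated)``.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    spike_times = np.asarray(spike_times, dtype=float)
    w0 = max(recording_start, onset - window)
    w = onset - w0
    truncated = w < window - 1e-12
    if w <= 0:
        return 0.0, truncated
    n = np.searchsorted(spike_times, onset) - np.searchsorted(spike_times, w0)
    return float(n / w * duration), truncated


@dataclass
class SignificanceResult:
    p: float
    lambda_used: float
    significant: bool
    alpha: float = DEFAULT_ALPHA


def poisson_response_test(
    count: int, mu: float, alpha: float = DEFAULT_ALPHA
) -> SignificanceResult:
    """Single-trial Poisson test of a stimulus-period spike count.

    p = P(X >= count) for X ~ Poisson(lambda) with lambda = mu floored
    at 1 when the background expectation is below one spike.
    """
    if count < 0 or int(count) != count:
        raise ValueError("count must be a nonnegative integer")
    if mu < 0:
        raise ValueError("mu must be >= 0")
    lam = mu if mu >= 1.0 else 1.0
    p = float(stats.poisson.sf(count - 1, lam))  # P(X >= count)
    return SignificanceResult(p=p, lambda_used=lam, significant=p < alpha, alpha=alpha)


def bonferroni_alpha(alpha: float, n_tests: int) -> float:
    """Corrected per-test cutoff when screening many presentations."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# selectivity
# ---------------------------------------------------------------------------


@dataclass
class SelectivityResult:
    r_loom: float
    r_other: float
    index: float | None
    included: bool
    reason: str = ""


def _corrected(count: float, mu: float) -> float:
    """Background-corrected count, clamped at zero."""
    return max(0.0, count - mu)


def selectivity_index(
    loom_count: int,
    loom_mu: float,
    other_count: int,
    other_mu: float,
    alpha: float = DEFAULT_ALPHA,
) -> SelectivityResult:
    """(r_L - r_O) / (r_L + r_O) from first-presentation counts.

    A neuron is included only if at least one of the two responses
    passes the Poisson significance criterion.
    """
    sig_l = poisson_response_test(loom_count, loom_mu, alpha).significant
    sig_o = poisson_response_test(other_count, other_mu, alpha).significant
    if not (sig_l or sig_o):
        return SelectivityResult(
            np.nan, np.nan, None, included=False, reason="neither response significant"
        )
    r_l = _corrected(loom_count, loom_mu)
    r_o = _corrected(other_count, other_mu)
    if r_l + r_o == 0:
        return SelectivityResult(r_l, r_o, None, included=False, reason="zero corrected counts")
    return SelectivityResult(r_l, r_o, (r_l - r_o) / (r_l + r_o), included=True)


def selectivity_vs_checkerboard(
    loom_count: int,
    loom_mu: float,
    mean_checker_rate_hz: float,
    loom_duration: float,
    alpha: float = DEFAULT_ALPHA,
) -> SelectivityResult:
    """Selectivity against the flickering checkerboard, where the
    comparison response is the mean checkerboard firing rate scaled to
    the loom duration: r_O = <r_C> t_L - mu."""
    sig_l = poisson_response_test(loom_count, loom_mu, alpha).significant
    checker_count = mean_checker_rate_hz * loom_duration
    sig_c = poisson_response_test(int(round(checker_count)), loom_mu, alpha).significant
    if not (sig_l or sig_c):
        return SelectivityResult(
            np.nan, np.nan, None, included=False, reason="neither response significant"
        )
    r_l = _corrected(loom_count, loom_mu)
    r_o = _corrected(checker_count, loom_mu)
    if r_l + r_o == 0:
        return SelectivityResult(r_l, r_o, None, included=False, reason="zero corrected counts")
    return SelectivityResult(r_l, r_o, (r_l - r_o) / (r_l + r_o), included=True)


# ---------------------------------------------------------------------------
# habituation and recovery
# ---------------------------------------------------------------------------


@dataclass
class HabituationResult:
    corrected: np.ndarray
    index: float | None
    i_used: int
    included: bool
    reason: str = ""


def habituation_index(
    counts, mu: float, i: int = 10, alpha: float = DEFAULT_ALPHA
) -> HabituationResult:
    """1 - r_i / r_1 over a repeated-loom series (i is 1-based).

    Included only when the first response is significant and its
    corrected count positive.  Corrected counts are clamped at 0, so
    complete habituation gives exactly 1; facilitation gives negative
    values.
    """
    counts = np.asarray(counts, dtype=float)
    if not 1 <= i <= len(counts):
        raise ValueError(f"trial index i={i} outside the series of {len(counts)}")
    corrected = np.maximum(0.0, counts - mu)
    if not poisson_response_test(int(counts[0]), mu, alpha).significant:
        return HabituationResult(corrected, None, i, False, "first response not significant")
    if corrected[0] <= 0:
        return HabituationResult(corrected, None, i, False, "first corrected count <= 0")
    return HabituationResult(corrected, 1.0 - corrected[i - 1] / corrected[0], i, True)


@dataclass
class RecoveryResult:
    fractions: np.ndarray  # r_i / r_1 per event (first entry 1)
    included: bool
    reason: str = ""


def recovery_curve(counts, mu: float, alpha: float = DEFAULT_ALPHA) -> RecoveryResult:
    """Per-neuron recovery fractions r_i / r_1 over the increasing-ISI
    loom series."""
    counts = np.asarray(counts, dtype=float)
    corrected = np.maximum(0.0, counts - mu)
    if not poisson_response_test(int(counts[0]), mu, alpha).significant:
        return RecoveryResult(np.full(len(counts), np.nan), False, "first response not significant")
    if corrected[0] <= 0:
        return RecoveryResult(np.full(len(counts), np.nan), False, "first corrected count <= 0")
    return RecoveryResult(corrected / corrected[0], True)


def recovery_percentiles(
    fractions: np.ndarray, q=(25, 50, 75)
) -> np.ndarray:
    """Population percentiles per event over neurons (rows = neurons)."""
    fractions = np.asarray(fractions, dtype=float)
    return np.nanpercentile(fractions, q, axis=0)


# ---------------------------------------------------------------------------
# receptive-field size from the random-loom grid
# ---------------------------------------------------------------------------


@dataclass
class RFEstimate:
    response: np.ndarray  # corrected max response per grid location
    locations: np.ndarray  # (n, 2) grid coordinates, deg
    center: np.ndarray  # response center of mass (deg)
    mean_radial_distance: float  # deg
    size: float  # 2 * Delta + spacing, deg
    spacing: float
    included: bool
    reason: str = ""


def rf_size(
    counts_per_location: dict | list,
    mus_per_location: dict | list,
    locations: np.ndarray,
    spacing: float = 15.0,
    alpha: float = DEFAULT_ALPHA,
    n_presentations: int | None = None,
) -> RFEstimate:
    """Receptive-field size from per-location loom responses.

    For each grid location, the response r(x) is the maximum spike
    count over repeats among trials that pass the (Bonferroni-
    corrected) Poisson criterion, minus the background expectation;
    non-significant locations are zeroed.  The field size is twice the
    response-weighted mean radial distance from the center of mass,
    plus the grid spacing (the spatial resolution of the measurement,
    so a single-location responder has size = spacing, not zero).

    ``counts_per_location`` / ``mus_per_location`` map location index
    to the per-repeat counts and backgrounds (parallel sequences).
    """
    locations = np.asarray(locations, dtype=float)
    n_loc = len(locations)
    if n_presentations is None:
        n_presentations = int(sum(len(np.atleast_1d(counts_per_location[i])) for i in range(n_loc)))
    a = bonferroni_alpha(alpha, max(1, n_presentations))
    r = np.zeros(n_loc)
    for i in range(n_loc):
        counts = np.atleast_1d(np.asarray(counts_per_location[i], dtype=float))
        mus = np.atleast_1d(np.asarray(mus_per_location[i], dtype=float))
        if mus.size == 1:
            mus = np.full(counts.shape, mus[0])
        best = 0.0
        for c, m in zip(counts, mus):
            if poisson_response_test(int(c), m, a).significant:
                best = max(best, _corrected(c, m))
        r[i] = best
    total = r.sum()
    if total <= 0:
        return RFEstimate(
            r, locations, np.full(2, np.nan), np.nan, np.nan, spacing,
            included=False, reason="no significant location",
        )
    center = (locations * r[:, None]).sum(axis=0) / total
    delta = float((np.linalg.norm(locations - center, axis=1) * r).sum() / total)
    return RFEstimate(r, locations, center, delta, 2.0 * delta + spacing, spacing, True)


# ---------------------------------------------------------------------------
# latency variability
# ---------------------------------------------------------------------------


@dataclass
class LatencyResult:
    latencies: np.ndarray  # first-spike times per included trial, s
    sd: float | None
    n_trials_used: int
    included: bool
    reason: str = ""


def latency_stats(
    spike_times: np.ndarray,
    onsets: np.ndarray,
    durations: np.ndarray,
    mus: np.ndarray,
    counts: np.ndarray | None = None,
    alpha: float = DEFAULT_ALPHA,
    min_trials: int = 5,
    min_latency: float = LATENCY_MIN_S,
) -> LatencyResult:
    """Variability of the first-spike latency over significant trials.

    A neuron is included only if (i) its background activity is below
    one spike per stimulus period and (ii) it responds significantly on
    at least ``min_trials`` trials.  Within each significant trial the
    latency is the first spike at least ``min_latency`` after onset
    (earlier spikes are unlikely to be stimulus-driven); trials with no
    qualifying spike contribute no latency.  The SD uses the n-1
    (sample) denominator.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    onsets = np.asarray(onsets, dtype=float)
    durations = np.asarray(durations, dtype=float)
    mus = np.asarray(mus, dtype=float)
    if counts is None:
        counts = np.array(
            [
                np.searchsorted(spike_times, o + d) - np.searchsorted(spike_times, o)
                for o, d in zip(onsets, durations)
            ]
        )
    counts = np.asarray(counts)
    if np.mean(mus) >= 1.0:
        return LatencyResult(np.empty(0), None, 0, False, "background activity >= 1")
    sig = np.array(
        [poisson_response_test(int(c), m, alpha).significant for c, m in zip(counts, mus)]
    )
    if sig.sum() < min_trials:
        return LatencyResult(
            np.empty(0), None, int(sig.sum()), False,
            f"fewer than {min_trials} significant trials",
        )
    lats = []
    for o, d in zip(onsets[sig], durations[sig]):
        in_win = spike_times[
            (spike_times >= o + min_latency) & (spike_times < o + d)
        ]
        if in_win.size:
            lats.append(in_win[0] - o)
    lats = np.asarray(lats)
    sd = float(np.std(lats, ddof=1)) if lats.size >= 2 else None
    return LatencyResult(lats, sd, int(sig.sum()), True)
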