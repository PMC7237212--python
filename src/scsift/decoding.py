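"""Population decoding of stimulus location and novelty.

In the random-loom experiment, looms appear at one of 25 grid
locations per trial.  Two questions are asked of the population spike
counts from single trials: *where* did the stimulus appear (25-way
classification) and *was it novel* — the first presentation at its
location (binary).  Decoders are L2-regularized logistic regressions
(C = 1, iteration cap 5000) on raw stimulus-period spike counts,
scored by mean 4-fold cross-validated accuracy.

Chance levels follow the label statistics: for location, the most
frequent location's trial share max_i n_i / sum_j n_j (~10% for 100
uniform trials over 25 locations); for novelty, the non-novel trial
share (~75%).

Because neurons recorded on one probe shank have overlapping receptive
fields, real populations are augmented with *virtual neurons*: copies
whose response profiles are shifted to the 8 neighbouring grid
locations of a 3 x 3 neighbourhood.  A virtual neuron's response to a
trial at location l is its source's response at l - shift — a pure
relabeling of recorded counts, never a resampling.  Copies whose
response profile would leave the stimulus presentation area are
discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score
from sklearn.model_selection import KFold, StratifiedKFold

from .metrics import DEFAULT_ALPHA, bonferroni_alpha, poisson_response_test
from .stimuli import Protocol


@dataclass
class DecodingDataset:
    """Trials x neurons spike counts with location/novelty labels."""

    X: np.ndarray  # (n_trials, n_neurons) nonnegative integers
    y_location: np.ndarray  # 1..n_locations
    y_novelty: np.ndarray  # 0/1
    groups: np.ndarray  # per-neuron layer label ('sSC' / 'dSC')
    grid: np.ndarray  # (n_locations, 2) grid coordinates
    trial_locations: np.ndarray  # (n_trials,) 0-based grid index
    mus: np.ndarray | None = None  # (n_trials, n_neurons) backgrounds

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        if np.any(self.X < 0):
            raise ValueError("spike counts must be nonnegative")


def novelty_labels(protocol: Protocol) -> np.ndarray:
    """1 iff no earlier trial used the same grid location."""
    from .population import novelty_flags

    return novelty_flags(protocol)


def location_labels(protocol: Protocol) -> np.ndarray:
    """1-based grid-location label per trial (row-major grid order)."""
    if protocol.grid is None:
        raise ValueError("protocol has no stimulus grid")
    grid = np.asarray(protocol.grid)
    out = np.empty(protocol.n_events, dtype=int)
    for k, ev in enumerate(protocol.events):
        d = np.linalg.norm(grid - np.asarray(ev.center), axis=1)
        i = int(np.argmin(d))
        if d[i] > 1e-6:
            raise ValueError(f"event {k} center {ev.center} is not a grid location")
        out[k] = i + 1
    return out


def build_decoding_dataset(
    trial_table: pd.DataFrame, protocol: Protocol
) -> DecodingDataset:
    """Pivot a trial table into the trials x neurons count matrix."""
    X = (
        trial_table.pivot(index="trial", columns="neuron", values="count")
        .sort_index()
        .to_numpy()
    )
    mus = (
        trial_table.pivot(index="trial", columns="neuron", values="mu")
        .sort_index()
        .to_numpy()
    )
    groups = (
        trial_table.drop_duplicates("neuron").sort_values("neuron")["layer"].to_numpy()
    )
    y_loc = location_labels(protocol)
    y_nov = novelty_labels(protocol)
    return DecodingDataset(
        X=X.astype(int),
        y_location=y_loc,
        y_novelty=np.asarray(y_nov, dtype=int),
        groups=groups,
        grid=np.asarray(protocol.grid),
        trial_locations=y_loc - 1,
        mus=mus,
    )


# ---------------------------------------------------------------------------
# virtual-neuron augmentation
# ---------------------------------------------------------------------------


@dataclass
class AugmentedPopulation:
    X: np.ndarray  # (n_trials, n_real + n_virtual)
    groups: np.ndarray
    sources: list[tuple[int, tuple[int, int]]]  # (source neuron, (dcol, drow))


def response_profile_support(
    X: np.ndarray,
    mus: np.ndarray,
    trial_locations: np.ndarray,
    n_locations: int,
    alpha: float = DEFAULT_ALPHA,
) -> list[set[int]]:
    """Grid locations with at least one significant response, per
    neuron (Bonferroni-corrected over presentations)."""
    n_trials, n_neurons = X.shape
    a = bonferroni_alpha(alpha, n_trials)
    support: list[set[int]] = [set() for _ in range(n_neurons)]
    for t in range(n_trials):
        for n in range(n_neurons):
            if poisson_response_test(int(X[t, n]), float(mus[t, n]), a).significant:
                support[n].add(int(trial_locations[t]))
    return support


def augment_population(
    dataset: DecodingDataset,
    grid_shape: tuple[int, int] = (5, 5),
    alpha: float = DEFAULT_ALPHA,
) -> AugmentedPopulation:
    """Add spatially shifted virtual copies of each neuron.

    Each neuron contributes up to 9 copies (the original plus the 8
    shifts of a 3 x 3 neighbourhood).  A copy is retained only if every
    location of the source's significant-response profile stays inside
    the presentation grid after the shift.  The copy's response to a
    trial at location l is taken from the source's trials at l - shift,
    matched in order of occurrence (cycled if the source has fewer
    trials there); trials whose shifted location falls outside the grid
    draw from the source's trials at locations outside its response
    profile, which by the retention rule carry only background
    activity.
    """
    rows, cols = grid_shape
    X, mus = dataset.X, dataset.mus
    if mus is None:
        raise ValueError("augmentation needs background expectations (mus)")
    n_trials, n_neurons = X.shape
    loc = dataset.trial_locations
    support = response_profile_support(X, mus, loc, rows * cols, alpha)

    # trials at each location, in order of occurrence
    trials_at: dict[int, list[int]] = {l: [] for l in range(rows * cols)}
    for t, l in enumerate(loc):
        trials_at[int(l)].append(t)

    def rc(l: int) -> tuple[int, int]:
        return l // cols, l % cols

    def idx(r: int, c: int) -> int:
        return r * cols + c

    cols_out = [X[:, n] for n in range(n_neurons)]
    groups_out = list(dataset.groups)
    sources: list[tuple[int, tuple[int, int]]] = [(n, (0, 0)) for n in range(n_neurons)]

    for n in range(n_neurons):
        bg_trials = [
            t for t in range(n_trials) if int(loc[t]) not in support[n]
        ]
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                ok = all(
                    0 <= r + dr < rows and 0 <= c + dc < cols
                    for r, c in (rc(l) for l in support[n])
                )
                if not ok:
                    continue
                v = np.empty(n_trials, dtype=X.dtype)
                per_loc_counter: dict[int, int] = {}
                bg_counter = 0
                for t in range(n_trials):
                    r, c = rc(int(loc[t]))
                    sr, sc = r - dr, c - dc
                    if 0 <= sr < rows and 0 <= sc < cols and trials_at[idx(sr, sc)]:
                        pool = trials_at[idx(sr, sc)]
                        k = per_loc_counter.get(idx(sr, sc), 0)
                        v[t] = X[pool[k % len(pool)], n]
                        per_loc_counter[idx(sr, sc)] = k + 1
                    elif bg_trials:
                        v[t] = X[bg_trials[bg_counter % len(bg_trials)], n]
                        bg_counter += 1
                    else:
                        v[t] = 0
                cols_out.append(v)
                groups_out.append(dataset.groups[n])
                sources.append((n, (dr, dc)))
    return AugmentedPopulation(
        X=np.column_stack(cols_out),
        groups=np.asarray(groups_out),
        sources=sources,
    )


# ---------------------------------------------------------------------------
# decoders
# ---------------------------------------------------------------------------


def chance_level(task: str, labels: np.ndarray) -> float:
    """Chance accuracy from the label statistics.

    location: share of the most frequent location; novelty: share of
    non-novel trials.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be nonempty")
    if task == "location":
        _, counts = np.unique(labels, return_counts=True)
        return float(counts.max() / counts.sum())
    if task == "novelty":
        return float(np.mean(labels == 0))
    raise ValueError(f"unknown task {task!r}")


def fit_decoder(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 4,
    seed: int = 0,
    max_redraws: int = 20,
) -> float:
    """Mean cross-validated accuracy of an L2 logistic regression.

    Folds are stratified by label when every class has at least
    ``folds`` members; otherwise seeded shuffled folds are drawn,
    redrawing (up to ``max_redraws`` times) if a training fold misses a
    class entirely.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() >= folds:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(splitter.split(X, y))
    else:
        splits = None
        for attempt in range(max_redraws):
            cand = list(
                KFold(n_splits=folds, shuffle=True, random_state=seed + attempt).split(X, y)
            )
            if all(len(np.unique(y[tr])) == len(classes) for tr, _ in cand):
                splits = cand
                break
        if splits is None:
            warnings.warn(
                "could not draw folds covering every class in training; "
                "using the last draw",
                stacklevel=2,
            )
            splits = cand
    scores = []
    for train, test in splits:
        clf = LogisticRegression(C=1.0, max_iter=5000)  # penalty defaults to l2
        clf.fit(X[train], y[train])
        scores.append(accuracy_score(y[test], clf.predict(X[test])))
    return float(np.mean(scores))


def subsample_curve(
    X: np.ndarray,
    y_location: np.ndarray,
    y_novelty: np.ndarray,
    groups: np.ndarray,
    sizes=(5, 10, 30, 70, 150, 300),
    reps: int = 100,
    folds: int = 4,
    seed: int = 0,
    tasks=("location", "novelty"),
) -> pd.DataFrame:
    """Decoding accuracy vs population size, per layer group.

    For each group and size, ``reps`` random subsamples of neurons are
    drawn and a decoder fit for each task; reported are the mean and SD
    of accuracy over subsamples together with the chance level.
    Sizes exceeding a group's population are skipped with a warning.
    """
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    rows = []
    ys = {"location": np.asarray(y_location), "novelty": np.asarray(y_novelty)}
    for g in pd.unique(groups):
        members = np.flatnonzero(groups == g)
        for size in sizes:
            if len(members) < size:
                warnings.warn(
                    f"group {g} has {len(members)} neurons < requested {size}; skipped",
                    stacklevel=2,
                )
                continue
            accs = {t: [] for t in tasks}
            for rep in range(reps):
                cols = rng.choice(members, size=size, replace=False)
                for t in tasks:
                    accs[t].append(
                        fit_decoder(X[:, cols], ys[t], folds=folds, seed=seed + rep)
                    )
            for t in tasks:
                a = np.asarray(accs[t])
                rows.append(
                    dict(
                        group=g,
                        size=size,
                        task=t,
                        accuracy_mean=float(a.mean()),
                        accuracy_sd=float(a.std(ddof=0)),
                        chance=chance_level(t, ys[t]),
                        reps=reps,
                    )
                )
    return pd.DataFrame(rows)
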