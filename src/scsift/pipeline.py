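"""Configuration, I/O and end-to-end pipeline runs.

A :class:`RunConfig` (YAML-serializable) fixes every parameter of a
simulated random-loom experiment: the protocol, the circuit model, the
synthetic population, the single-neuron analyses and the decoding.
:func:`run_pipeline` executes protocol -> spikes -> trial table ->
metrics -> decoding and writes each product plus a manifest with
content hashes; every stochastic stage derives its seed from the
master seed, so identical configs give byte-identical outputs.

Spike times are stored in seconds at 1 microsecond precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import circuit as cm
from . import decoding as dec
from . import metrics as mx
from . import population as pop
from .stimuli import Protocol, random_loom_protocol

log = logging.getLogger("scsift")

TIME_FORMAT = "%.6f"  # 1 us resolution


@dataclass
class RunConfig:
    """Master configuration of a pipeline run."""

    seed: int = 0
    # protocol
    n_trials: int = 100
    isi_s: float = 3.0
    grid_shape: tuple[int, int] = (5, 5)
    spacing_deg: float = 15.0
    # circuit
    tau_rec_s: float = 180.0
    depression_gain: float = 1.0
    w_min: float = 0.0
    loom_response_integral: float = 4.0
    # population
    n_ssc: int = 60
    n_dsc: int = 60
    span_deg: float = 60.0
    # analysis
    alpha: float = 0.005
    background_window_s: float = 5.0
    habituation_i: int = 10
    # decoding
    subsample_sizes: tuple[int, ...] = (5, 10, 30)
    subsample_reps: int = 20
    folds: int = 4
    # output
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("grid_shape", "subsample_sizes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(d["grid_shape"])
        d["subsample_sizes"] = list(d["subsample_sizes"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def circuit_config(self) -> cm.CircuitConfig:
        return cm.CircuitConfig(
            grid_shape=self.grid_shape,
            spacing=self.spacing_deg,
            tau_rec=self.tau_rec_s,
            a=self.depression_gain,
            w_min=self.w_min,
            loom_response_integral=self.loom_response_integral,
        )

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# recording I/O
# ---------------------------------------------------------------------------


def write_recording(recording: pop.PopulationRecording, outdir) -> dict[str, Path]:
    """Write a recording as spikes.csv + neurons.csv + protocol.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "spikes": outdir / "spikes.csv",
        "neurons": outdir / "neurons.csv",
        "protocol": outdir / "protocol.json",
    }
    rows = [
        (int(recording.neurons.iloc[i]["neuron"]), t)
        for i in range(recording.n_neurons)
        for t in recording.spikes[i]
    ]
    df = pd.DataFrame(rows, columns=["neuron_id", "time_s"])
    df.to_csv(paths["spikes"], index=False, float_format=TIME_FORMAT)
    recording.neurons.to_csv(paths["neurons"], index=False, float_format="%.6f")
    paths["protocol"].write_text(recording.protocol.to_json())
    return paths


def read_recording(spikes_path, neurons_path, protocol_path) -> pop.PopulationRecording:
    """Read a recording written by :func:`write_recording`.

    Malformed rows raise with their line numbers; unsorted spike times
    are sorted with a warning.
    """
    neurons = pd.read_csv(neurons_path)
    protocol = Protocol.from_json(Path(protocol_path).read_text())
    raw = pd.read_csv(spikes_path)
    if list(raw.columns) != ["neuron_id", "time_s"] and not raw.empty:
        raise ValueError(f"{spikes_path}: expected columns neuron_id,time_s")
    bad = raw.index[raw.isna().any(axis=1)]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:5])  # +2: header and 1-based
        raise ValueError(f"{spikes_path}: malformed rows at lines {lines}")
    spikes = []
    for nid in neurons["neuron"].astype(int):
        t = raw.loc[raw["neuron_id"] == nid, "time_s"].to_numpy(float)
        if t.size and np.any(np.diff(t) < 0):
            warnings.warn(f"spike times for neuron {nid} unsorted; sorting", stacklevel=2)
            t = np.sort(t)
        spikes.append(t)
    return pop.PopulationRecording(spikes=spikes, neurons=neurons, protocol=protocol)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict:
    """Run the full simulated random-loom experiment.

    Stages: protocol -> population -> spikes -> trial table ->
    single-neuron metrics (receptive-field size, latency variability,
    habituation at repeated locations) -> location/novelty decoding.
    Returns the manifest (also written to the output directory).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        log.info("stage: %s", name)

    stage("protocol")
    protocol = random_loom_protocol(
        n_trials=config.n_trials,
        isi=config.isi_s,
        grid_shape=config.grid_shape,
        spacing=config.spacing_deg,
        seed=config.stage_seed("protocol"),
    )

    stage("population")
    neurons = pop.make_population(
        config.n_ssc, config.n_dsc, span=config.span_deg, seed=config.stage_seed("population")
    )

    stage("spikes")
    ccfg = config.circuit_config()
    try:
        recording = pop.generate_spikes(
            neurons, protocol, seed=config.stage_seed("spikes"), config=ccfg
        )
    except Exception as err:  # pragma: no cover - defensive
        raise RuntimeError(f"stage 'spikes' failed for protocol seed {protocol.seed}") from err
    paths = write_recording(recording, outdir)

    stage("trial_table")
    table = pop.build_trial_table(recording, protocol, config.background_window_s)
    paths["trial_table"] = outdir / "trial_table.csv"
    table.to_csv(paths["trial_table"], index=False, float_format="%.6f")

    stage("metrics")
    grid = np.asarray(protocol.grid)
    loc_index = dec.location_labels(protocol) - 1
    rf_rows, lat_rows = [], []
    for nid, sub in table.groupby("neuron"):
        sub = sub.sort_values("trial")
        counts_by_loc = {i: [] for i in range(len(grid))}
        mus_by_loc = {i: [] for i in range(len(grid))}
        for t, row in enumerate(sub.itertuples()):
            counts_by_loc[int(loc_index[t])].append(row.count)
            mus_by_loc[int(loc_index[t])].append(row.mu)
        est = mx.rf_size(
            [counts_by_loc[i] for i in range(len(grid))],
            [mus_by_loc[i] for i in range(len(grid))],
            grid,
            spacing=config.spacing_deg,
            alpha=config.alpha,
            n_presentations=len(sub),
        )
        rf_rows.append(
            dict(
                neuron=nid,
                layer=sub["layer"].iloc[0],
                size_deg=est.size,
                included=est.included,
                reason=est.reason,
            )
        )
        spk = recording.spikes[int(nid)]
        lat = mx.latency_stats(
            spk,
            sub["onset"].to_numpy(),
            sub["duration"].to_numpy(),
            sub["mu"].to_numpy(),
            counts=sub["count"].to_numpy(),
            alpha=config.alpha,
        )
        lat_rows.append(
            dict(
                neuron=nid,
                layer=sub["layer"].iloc[0],
                latency_sd_s=lat.sd if lat.sd is not None else np.nan,
                n_trials_used=lat.n_trials_used,
                included=lat.included,
                reason=lat.reason,
            )
        )
    paths["rf_size"] = outdir / "rf_size.csv"
    pd.DataFrame(rf_rows).to_csv(paths["rf_size"], index=False, float_format="%.6f")
    paths["latency"] = outdir / "latency.csv"
    pd.DataFrame(lat_rows).to_csv(paths["latency"], index=False, float_format="%.6f")

    stage("decoding")
    ds = dec.build_decoding_dataset(table, protocol)
    sizes = [s for s in config.subsample_sizes]
    curve = dec.subsample_curve(
        ds.X,
        ds.y_location,
        ds.y_novelty,
        ds.groups,
        sizes=sizes,
        reps=config.subsample_reps,
        folds=config.folds,
        seed=config.stage_seed("decoding"),
    )
    paths["decoding"] = outdir / "decoding.csv"
    curve.to_csv(paths["decoding"], index=False, float_format="%.6f")

    stage("manifest")
    config_path = outdir / "config.yaml"
    config.to_yaml(config_path)
    paths["config"] = config_path
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {
            s: config.stage_seed(s) for s in ("protocol", "population", "spikes", "decoding")
        },
        "files": {name: _sha256(p) for name, p in sorted(paths.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
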