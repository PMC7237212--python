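# scsift

Simulation and analysis of **visual sifting in the mouse superior
colliculus (SC)**: how, between the retinorecipient superficial layers
(sSC) and the deep layers (dSC), neural responses become selective for
a behaviourally urgent stimulus — an expanding dark disk ("looming",
the signature of an approaching overhead object — invariant to where
that stimulus appears, and suppressed when the stimulus repeats at a
familiar location.

The package is aimed at systems neuroscientists who want a tested,
reusable implementation of the stimulus protocols, the circuit model,
and the spike-train statistics of this paradigm, together with a
synthetic population generator so that every analysis can be exercised
end-to-end without recorded data.

## What is inside

| module | contents |
| --- | --- |
| `scsift.stimuli` | stimulus movies (looming, contracting, dimming, translating disks; flickering checkerboards) and trial protocols (repeated loom, 5×5-grid "random loom", increasing-ISI recovery series) |
| `scsift.circuit` | the LN-cascade circuit model with short-term synaptic depression |
| `scsift.population` | synthetic sSC/dSC populations with inhomogeneous-Poisson spiking |
| `scsift.metrics` | Poisson significance test, selectivity / habituation / recovery indices, receptive-field size, latency variability |
| `scsift.sta` | spike-triggered averages and SVD space-time separation |
| `scsift.decoding` | location (25-way) and novelty (binary) population decoders, virtual-neuron augmentation, chance levels |
| `scsift.pipeline`, `scsift.cli` | YAML-configured end-to-end runs (`scsift run`), CSV/JSON I/O, manifests |

## The model

Each retinal input is a linear–nonlinear element: a drive
`g(t) = s(x,y,t) * k(x,y,t)` (space–time convolution of the Weber
contrast field with a separable kernel `k = F(x,y)·T(t)`), passed
through a half-wave rectifier `N(g) = max(0, m·g − θ)`.  `F` is an
isotropic Gaussian (σ = 4° center, 10° surround); `T` is the biphasic
difference of two gamma-like lobes fitted to mouse alpha retinal
ganglion cells.

A **local looming detector** combines a fast transient center with a
slow sustained surround, `r_LD(t) = N(r_c(t) − r_s(t))`: only an
expanding dark edge drives the center before the surround vetoes it.
Detectors tile the field on a 15° grid and converge on a **widefield
neuron**, `r_WF(t) = Σ_i w_i·r_LD,i(t)`, through synapses with
short-term depression

```
dw/dt = (1 − w)/τ − a·(w − w_min)·r(t)
```

(depression gain `a = 1`, floor `w_min = 0`, recovery `τ = 180 s`).
One centered loom nearly exhausts its local synapse (the "depression
dose" ∫a·r dt ≈ 4), producing habituation that is immediate,
location-specific, and recovers over minutes — while looms at other
grid points still fire the widefield neuron at full strength with the
same latency.

Analyses follow one response definition throughout: the spike count
r′ during the stimulus period, compared against the background
expectation μ (baseline rate × stimulus duration) with a Poisson test
whose mean is floored at one spike (cutoff p < 0.005, Bonferroni
corrected across presentations).

## Worked example

Ten identical looms, 2 s apart, watched by one superficial and one
deep neuron:

```python
from scsift import stimuli, population, metrics

protocol = stimuli.repeat_loom_protocol(n_trials=10, isi=2.0, location=(0.0, 0.0))
neurons = population.make_population(n_ssc=1, n_dsc=1, span=8.0, seed=1)
recording = population.generate_spikes(neurons, protocol, seed=0)
table = population.build_trial_table(recording, protocol)
for nid, sub in table.groupby("neuron"):
    sub = sub.sort_values("trial")
    counts = sub["count"].to_numpy()
    result = metrics.habituation_index(counts, sub["mu"].iloc[0])
    print(f"{sub['layer'].iloc[0]} neuron: counts per trial = {counts.tolist()}, "
          f"habituation index = {result.index:.2f}")
```

prints

```
sSC neuron: counts per trial = [22, 16, 20, 17, 16, 16, 21, 15, 26, 15], habituation index = 0.32
dSC neuron: counts per trial = [13, 0, 1, 0, 0, 0, 0, 0, 1, 1], habituation index = 0.92
```

The superficial neuron fires a burst on every repeat (its habituation
index, `1 − r_10/r_1` with background-corrected counts, fluctuates
around 0), while the deep neuron responds essentially once: its
depressing synapse silences every later repeat, giving an index near
1.

The same populations run through the random-loom experiment yield the
full sifting picture: superficial receptive fields of ~15–45° versus
deep fields above 60°, and a decoding double dissociation — stimulus
*location* is read out accurately from sSC but not dSC spike counts,
stimulus *novelty* from dSC but barely from sSC.  `scsift run
--outdir results` executes that whole pipeline from one seed.

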