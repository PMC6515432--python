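# caflux

Single-cell calcium-activity analysis for time-lapse fluorescence imaging of
developing neural tissue.

Embryonic neurons and their progenitors show spontaneous calcium transients
whose frequency and shape are thought to influence neurotransmitter fate.
`caflux` takes the per-cell fluorescence time series exported by tracking
software (one CSV column per ROI), removes slow drift, quantifies each cell's
activity with four complementary metrics, scores each cell's marker-gene
expression from FISH intensities, and asks whether phenotype-defined cell
populations differ in their calcium dynamics — with an effect-size gate so
that large samples alone cannot manufacture significance. A synthetic-data
generator with full ground truth stands in for microscopy data, so every
stage is testable end to end.

## The metrics

For a detrended trace *x₁…x_T* (frame interval 8 s, i.e. 0.125 Hz; cells must
be tracked for ≥ 600 contiguous frames):

* **Spike frequency** — baseline *B* = mean of all time points; a spike at
  threshold *m* is a maximal run of ≥ 2 consecutive frames with *xᵢ ≥ mB*,
  evaluated at *m* = 1.25, 1.5, 2, 3, 4 and 8, reported in spikes per hour.
* **Average power** — *P = (1/T) Σ Xᵢ²* with *Xᵢ = xᵢ/x̄ − 1*, a
  threshold-free fluctuation-energy index.
* **Hurst exponent** — rescaled-range (R/S) analysis over dyadic window
  lengths; *H* = ½ + slope of log₂(mean R/S) − log₂ E[R/S] against
  log₂(window length), where E[R/S] is the Anis–Lloyd small-sample
  expectation. *H* ≈ 0.5 is memoryless; *H* > 0.5 persistent.
* **Markovian entropy** — the trace is binned into *n* = 4 quantile states,
  the *nᵏ* × *n* transition matrix (*k* = 1) is formed, and the summed row
  entropies *E = −Σ Pᵢ log₂ Pᵢ* are normalized by *nᵏ log₂ n*, giving a
  predictability score in [0, 1].

FISH phenotype: each cell's mean intensity *F* is divided by the plate
background *F₀* (mean of the five dimmest cells); a cell is marker-positive
when *F/F₀* ≥ 2 (3× and 4× evaluated alongside). Two populations differ on a
metric only if the Bonferroni-adjusted two-sample Kolmogorov–Smirnov *p* < 0.05
**and** |Cohen's *d*| > 0.2.

## Worked example

```python
from caflux import (FishModel, compute_cell_metrics, compute_fish_scores,
                    join_phenotype, run_comparison_design, shuffle_control)
from caflux.synth import (progenitor_like_spec, differentiated_like_spec,
                          generate_population)
from caflux.preprocess import detrend_asls, filter_contiguous_tracks

fm = FishModel(positive_fraction=0.8, positive_score_mean=3.0)
spec_a = progenitor_like_spec(n_cells=40, seed=11, fish_model=fm)   # frequent small spikes
spec_b = differentiated_like_spec(n_cells=40, seed=12, fish_model=fm)  # sparse large spikes
data = generate_population(spec_a, spec_b, labels=("gad1.1", "slc17a7"))

kept, dropped = filter_contiguous_tracks(data["traces"])
detrended = [detrend_asls(t) for t in kept]
metrics = [compute_cell_metrics(d) for d in detrended]

joined = {}
for label in data["labels"]:
    records = compute_fish_scores(data["fish"][label])
    joined[label], _ = join_phenotype(metrics, records, data["roi_maps"][label])

results = run_comparison_design((joined["gad1.1"], joined["slc17a7"]),
                                "posA_vs_posB", ("gad1.1", "slc17a7"))
ctrl = shuffle_control(detrended, seed=0)
```

This prints (via the cell metrics and comparison rows):

```
gad1.1_0000: 14.5 spikes/h at 1.25x, power 0.0291, H 0.56, entropy 0.98
spikes_per_hour_1.25x: D=1.00, p_adj=0.00e+00, d=+4.97, significant=True
spikes_per_hour_3x:    D=1.00, p_adj=0.00e+00, d=-5.88, significant=True
shuffle control: H = 0.490 +/- 0.035, entropy = 0.996 +/- 0.002
```

The sign of Cohen's *d* flips between the 1.25× and 3× spike thresholds: the
progenitor-like population dominates low-amplitude spiking while the
differentiated-like population dominates high-amplitude spiking — the
threshold-dependent pattern the comparison design is built to expose. The
shuffle control destroys sequential structure, driving the Hurst estimate to
~0.5 and the entropy to ~1, which is the calibration expected of both metrics
on memoryless data.

The same analysis runs from the command line:

```bash
caflux synth --out data/ --seed 3          # synthetic two-population dataset
caflux run --config run.yaml               # full pipeline -> CSV reports + manifest
caflux controls --config run.yaml          # randomization controls only
```

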