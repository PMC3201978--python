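# calsig

Kinetic analysis and population comparison of intracellular Ca²⁺
fluorescence traces.

Astrocytes (and many other non-excitable cells) respond to
neurotransmitters such as ATP, glutamate and histamine with global
intracellular Ca²⁺ elevations whose time courses are strikingly
heterogeneous: single spikes, bursts, repetitive oscillations, sustained
plateaus. `calsig` is a pipeline for asking whether that heterogeneity is
systematic — whether the *shape* of the Ca²⁺ response carries information
about the stimulus. It is aimed at imaging labs who have already reduced
their movies to per-cell fluorescence time series (e.g. fluo-4 intensity
per nucleus-centred ROI) and need the downstream analysis.

## What it computes

**Normalization and kinetics.** Each trace is expressed as
F/F₀, with F₀ the mean intensity over the 20 s before agonist addition.
Cells are *responders* when F/F₀ exceeds 1.045-fold after the stimulus
(≈3 SD above baseline noise); cells already active before the stimulus
are flagged and set aside. For each responder the pipeline measures
peak amplitude (F`max`/F₀), rise time (10%→90% of the
baseline-subtracted peak, linearly interpolated), latency (stimulus to
the 10% crossing) and AUC (trapezoidal integral from the 10% crossing to
the end of the recording).

**Spike detection and classification.** For long-term recordings the
trace is detrended by subtracting a centred moving average (50 samples);
maximal excursions above 0.4 lasting ≥5 s are spikes. Responses are
sorted by spike count n, mean interspike interval (ISI) and AUC into
four classes:

| class | rule |
|---|---|
| single spike (SS) | n = 1 and AUC < 500 |
| burst of spikes (BS) | n > 1, ISI·n ≤ 300 and AUC > 1000 |
| repetitive spikes (RS) | n > 1 and ISI·n > 300 |
| sustained (SU) | n = 1 and AUC > 500 |

Combinations matching no rule are UNCLASSIFIED.

**Population difference.** Two populations of a kinetic parameter are
compared by binning both on shared equal-width edges (default 50 bins
over the pooled range), normalizing each histogram to unit mass, and
computing

&nbsp;&nbsp;&nbsp;&nbsp;*D* = ½ Σᵢ |Aᵢ − Bᵢ|,

the total variation distance between the binned distributions: 0 for
identical populations, 1 for disjoint ones. Gaussian surrogate
populations (n = 5000, unit SD) with means offset by 1, 2 and 3 SD give
*D* ≈ 0.37, 0.68 and 0.87, anchoring interpretation; same-distribution
draws sit near the ~0.15 background level. Class-proportion tables are
compared with an exact Fisher test (full enumeration). A seeded
synthetic-trace generator provides labelled data for all four archetypes
so the whole pipeline is testable without real recordings.

## Worked example

```python
from calsig import (generate_cohort, normalize, classify_population,
                    gaussian_calibration, long_term_config)

cfg = long_term_config()                       # 20-min / 2 Hz workflow
traces, truth = generate_cohort(n_per_class=3, seed=42)
frame, counts = classify_population([normalize(t, cfg) for t in traces], cfg)
print(frame.head(4).to_string(index=False))
print({c.value: n for c, n in counts.items()})
```

```
cell_id  spike_count  mean_isi_s         auc label
 SS_000            1         NaN   67.392642    SS
 SS_001            1         NaN   62.000278    SS
 SS_002            1         NaN   73.513920    SS
 BS_000            3       31.75 1502.351399    BS
{'SS': 3, 'BS': 3, 'RS': 3, 'SU': 3, 'UNCLASSIFIED': 0}
```

All twelve synthetic cells recover their generating archetype: the SS
cells show one spike with small baseline-subtracted AUC, the BS cells
several closely spaced spikes on a large-AUC envelope, and so on. The
surrogate calibration reproduces the interpretive anchors:

```python
print(gaussian_calibration([1.0, 2.0, 3.0], n=5000, n_seeds=10, seed=0)
      [["offset_sd", "mean_d", "sd_d"]].round(3).to_string(index=False))
```

```
 offset_sd  mean_d  sd_d
       1.0   0.384 0.012
       2.0   0.683 0.008
       3.0   0.866 0.004
```

i.e. unit-variance Gaussian populations whose means differ by 1, 2 and
3 SD are *D* ≈ 0.38, 0.68 and 0.87 apart — so a measured *D* of, say,
0.25 between two agonists means their response distributions overlap far
too much for a cell to tell them apart from a single response.

The same stages are available from the shell:

```bash
calsig simulate --n-per-class 50 --seed 1 --out traces.csv
calsig classify traces.csv --stim-time 30 --out labels.csv
calsig extract traces.csv --stim-time 30 --out features.csv
calsig compare features_a.csv features_b.csv --parameter auc --out d.csv
calsig calibrate --offsets 1,2,3 --out calibration.csv
```

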