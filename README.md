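# mstate

EEG microstate analysis of within-subject emotion conditions, built as an
importable Python library with a fully synthetic validation path.

Scalp EEG alternates between quasi-stable potential topographies
("microstates", canonically four classes A–D) that persist ~100 ms before
switching. This package implements the classical analysis chain for
comparing microstate dynamics across emotion conditions in a repeated-
measures design — and, because such studies' recordings are rarely public,
a synthetic-EEG generator with *planted, recoverable* microstate structure
so every stage can be validated against ground truth.

The chain:

1. **Preprocessing** — zero-phase FIR band-pass (3–80 Hz broadband;
   theta/alpha/beta/gamma band split at 4–8/8–13/13–30/30–49 Hz),
   fixed-window epoching, rejection of epochs exceeding ±100 μV, average
   referencing, baseline (epoch-mean) removal.
2. **Clustering** — global field power GFP(t) = √((1/N)Σₙ(Uₙ−Ū)²); the
   topographies at GFP local maxima are clustered by AAHC (agglomeration
   by least loss of global explained variance, GEV), ignoring polarity.
3. **Template hierarchy** — trial → condition → global template
   averaging with optimal label matching, then back-fitting: each sample
   labeled by the template of highest absolute spatial correlation.
4. **Features** — per class: mean duration (ms), occurrence (1/s),
   coverage (%), plus the 12 conditional transition probabilities
   (24 features for K = 4).
5. **Statistics** — normality-gated Friedman vs one-way repeated-measures
   ANOVA with Mauchly/Greenhouse–Geisser/Huynh–Feldt handling and
   Bonferroni post hocs for duration/occurrence/coverage; paired
   t / Wilcoxon against the neutral condition for transitions; bands whose
   mean GEV is below 70% are excluded; noncentral-t/F sample-size
   (power) computations.

See `docs/methods.md` for the model, conventions and numerical choices.

## Worked example

```python
from mstate import SimConfig, aahc, extract_peak_maps, generate_study

cfg = SimConfig(seed=3, n_channels=59, n_subjects=1,
                n_trials_per_condition=1, snr=4.0)
study = generate_study(cfg)
maps, weights, peaks = extract_peak_maps(study.epochs[0])
templates = aahc(maps, k_target=4, gfp_weights=weights)
print(len(peaks), round(templates.gev, 3))
```

Running `python examples/cluster_microstates.py` (the same computation,
plus scoring against the planted maps) prints:

```
epoch of 2 s at 250 Hz: 47 GFP peaks
AAHC at K=4: GEV = 0.971 (fraction of GFP-weighted topographic variance explained)
  centroid A <-> planted map 2: |r| = 0.996
  centroid B <-> planted map 0: |r| = 0.998
  centroid C <-> planted map 3: |r| = 0.999
  centroid D <-> planted map 1: |r| = 0.998
```

A 2-s epoch with a 10 Hz carrier has ~40–47 usable GFP peaks (two per
cycle); clustering them explains 97% of the GFP-weighted variance, and
each recovered centroid matches one planted template almost perfectly
(class order is arbitrary until the sorting stage aligns it).

Other examples, one per capability: `simulate_study.py`,
`extract_features.py`, `full_pipeline.py`, `power_analysis.py`. A thin
CLI wraps the same functions:

```sh
mstate simulate --out data/ --seed 1
mstate run --out results/ --manifest data/manifest.csv --band alpha
mstate power paired_t -e 0.5
```

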