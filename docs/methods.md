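# Methods

## Background and model

EEG microstate analysis describes multichannel scalp EEG as a sequence of
quasi-stable potential topographies ("microstates") that persist on the
order of 100 ms before switching abruptly. The analysis rests on three
quantities:

* **Global field power (GFP).** For an average-referenced sample with
  potentials U_n(t) over N electrodes,

      GFP(t) = sqrt( (1/N) Σ_n (U_n(t) − Ū(t))² ),

  the uncorrected population standard deviation across channels.
  Topographies at GFP local maxima have the highest spatial
  signal-to-noise ratio and are the only samples used for clustering.

* **Polarity invariance.** A topography and its sign-flipped copy are the
  same microstate (oscillatory generators flip polarity every
  half-cycle), so every spatial comparison uses the absolute Pearson
  correlation across channels, and cluster centroids are sign-aligned
  means.

* **Global explained variance (GEV).** For maps u_t with weights GFP_t
  assigned to templates T_a(t),

      GEV = Σ_t (GFP_t · C(u_t, T_a(t)))² / Σ_t GFP_t²,

  where C is the absolute spatial correlation of the zero-mean,
  unit-norm maps. GEV is the fraction of GFP-weighted topographic
  variance the template set explains; a band whose mean GEV falls below
  70% is conventionally excluded from microstate interpretation, and the
  pipeline applies that gate (threshold configurable).

## Clustering (AAHC)

Clustering starts from one cluster per GFP-peak map and agglomerates down
to K classes (default K = 4, the canonical A–D set). The default schedule
merges, at each step, the **pair** of clusters whose union loses the least
GEV, evaluating the union's actual centroid (members sign-aligned,
averaged, recentred, renormalized). Exact pairwise accounting matters: a
cheaper one-cluster "atomization" criterion scores orphaned members
against the *current* centroids of other clusters and therefore
underestimates what a genuine merge retains — on separable test instances
it sometimes dissolves a correctly-isolated small cluster while a dominant
state stays split in two. Both atomization variants remain available
(`criterion="gev_loss"` with one-step lookahead, `criterion="contribution"`
for the classical least-contribution rule); the merge schedule is the one
verified against exhaustive partition search (50 random separable
instances, 2–4 orthogonal templates, up to 9 maps: optimal GEV attained in
all). Ties in the merge cost break toward lower cluster indices, making
the result deterministic for a given input order.

## Template hierarchy and back-fitting

Templates are estimated per trial, averaged into per-emotion-condition
sets, and those into one global set. Before averaging, sets are aligned by
optimal one-to-one matching on the absolute-correlation matrix (Hungarian
algorithm — exact for any K; greedy matching can fail on correlated maps)
and sign-aligned map-by-map. Labels propagate back down: condition sets
are sorted against the global set, trial sets against their condition set,
so class "A" denotes the same topography at every level.

Back-fitting labels each sample with the template of highest absolute
spatial correlation; samples with zero GFP are UNASSIGNED. Two modes:

* `samplewise` — every sample labeled independently.
* `peaks` — labels computed at GFP maxima and propagated outward to the
  midpoint between adjacent peaks.

Near oscillation zero-crossings the instantaneous topography is noise-
dominated, so samplewise labels fragment into very short runs there;
peak-propagation is the appropriate mode whenever dynamics (durations,
transitions) are the target, and is what the parameter-recovery tests use.
No temporal smoothing or minimum-duration rejection is applied.

## Features

A label sequence decomposes into maximal runs. Per class k:
duration (mean run length, ms), occurrence (runs per second of *labeled*
time, so unassigned samples do not dilute rates), coverage (% of labeled
samples), and the conditional transition probabilities P(i→j) over
adjacent runs — 4 + 4 + 4 + 12 = 24 features for K = 4. Conventions, all
configurable where marked:

* terminal runs have no successor and are excluded from transition
  denominators; a class with no outgoing transition has a NaN row;
* UNASSIGNED gaps split runs and break transition adjacency;
* runs truncated by epoch edges are included (flag `drop_boundary_runs`);
* transitions are row-normalized conditional probabilities (flag
  `joint_transitions` for joint frequencies).

With a fully labeled epoch, occurrence × duration = coverage exactly;
with gaps or dropped boundary runs the identity holds to O(1/#runs).

Valence ratings (1–9) map to emotion conditions as 1–3 negative, 4–5
neutral, 6–9 positive; per-trial features are averaged per
subject × emotion, and subjects lacking an emotion entirely are flagged
and excluded from the repeated-measures statistics (which need complete
cases).

## Statistics

Duration/occurrence/coverage are compared across the three emotions with
a normality-gated scheme: Shapiro–Wilk per condition at α = 0.05; if all
pass, a one-way repeated-measures ANOVA (direct within-subject SS
decomposition; partial η² effect size), otherwise the Friedman rank test
(mid-ranks, tie-corrected χ²; Kendall's W as the descriptive effect size).
Mauchly's test gates the sphericity correction: when it rejects at 0.05,
degrees of freedom are multiplied by the Huynh–Feldt ε if the
Greenhouse–Geisser ε exceeds 0.75, else by the Greenhouse–Geisser ε
(ε values from pingouin; HF clipped at 1). Significant omnibus tests are
followed by Bonferroni-corrected pairwise post hocs. Transition
probabilities are compared with two-sided paired t-tests (Cohen's d_z)
against the neutral reference, replaced by Wilcoxon signed-rank tests
(zeros dropped; exact null for small untied samples; rank-biserial effect
size) when the differences fail Shapiro–Wilk. No multiplicity adjustment
is applied across the 12 transition features by default.

The Friedman p-value comes from the χ²(m−1) approximation by default; an
exact mode enumerates all (m!)^n within-subject rank orders (feasible to
~100k configurations) and is verified against an independent enumeration
oracle in the tests.

Prospective sample sizes invert power functions computed from noncentral
distributions, following the conventions of the G*Power tool: for the
paired t-test, noncentrality d·√n with df = n−1; for the within factor of
a one-group repeated-measures ANOVA, λ = f²·N·m·ε/(1−ρ), df₁ = (m−1)ε,
df₂ = (N−1)(m−1)ε. At (d = 0.5, α = 0.05, power 0.8, two-sided) the
smallest n is 34; at (f = 0.25, m = 3, ρ = 0.5, ε = 1) it is 28; in both
designs n−1 falls below the target power (exact-inversion property,
tested).

## Synthetic data

The generator realizes the forward model the analysis assumes:

* **Templates** — K orthonormal zero-mean random topographies (the
  average-reference constraint leaves an (N−1)-dimensional subspace, so
  K ≤ N−1). Orthogonality makes instances separable; per-subject
  variability is a small random rotation (default 5°, implemented as
  noise-plus-reorthonormalization) so cross-subject averaging is
  non-trivial. Real microstate maps are smooth dipolar fields on a
  montage; random orthogonal vectors are *harder* to distinguish under
  volume-conduction-like noise smoothing than real maps are, not easier.
* **Dynamics** — a hidden Markov chain with geometric (memoryless) run
  lengths, mean dwell configurable per condition (defaults 140 / 125 /
  110 ms for negative / neutral / positive; ~100–150 ms is the
  physiological range), and a row-stochastic zero-diagonal transition
  matrix (default uniform off-diagonal).
* **Carrier** — the active template is modulated by sin(2πft) (default
  f = 10 Hz, alpha). The *envelope* is the rectified |sin|, so GFP maxima
  are dense (two per cycle) and aligned with carrier extrema; using the
  signed waveform rather than its rectification keeps the spectral energy
  at f — a rectified carrier has energy only at DC and even harmonics,
  and band-pass filtering at the carrier band would annihilate the
  planted structure. Under polarity invariance the sign is invisible to
  every downstream stage (`rectified_carrier=True` restores the strictly
  nonnegative envelope).
* **Noise** — white Gaussian noise smoothed by a moving average over a
  circular channel ring (width 5; a crude volume-conduction surrogate;
  width 1 gives iid noise), re-referenced and scaled so
  RMS(signal)/RMS(noise) equals the requested SNR (default 4).
* **Seeding** — one master seed; subject/trial child generators derive by
  fixed offsets; identical configs reproduce bit-identical studies.

What the generator does **not** emulate: realistic head geometry and
channel covariance, eye/muscle artifacts, line noise, non-stationary
dwell distributions, inter-trial template drift. Passing recovery tests
therefore demonstrate the *estimator chain* is correct and unbiased under
the model's assumptions, not that real recordings satisfy those
assumptions.

## Problem sizes and numerical choices

* Parameter-recovery validation runs 40 independent studies of
  10 subjects × 3 conditions × 5 trials (2-s epochs, 59 channels,
  250 Hz, SNR 4), analyzed in the alpha band with peak-mode back-fitting.
  Pooled transition estimates are required to be unbiased (seed-averaged
  within ±0.05 of the planted matrix) and the planted duration ordering
  (negative > positive) to be recovered in ≥95% of studies. A per-study
  max-deviation bound of 0.05 would not be meaningful at this scale: a
  single study yields ~2 250 run transitions, so the realized chain's own
  sampling error is ~0.02 per cell and the max over 12 cells crosses 0.05
  in a substantial fraction of studies even when back-fitting with the
  true templates.
* The hierarchy round-trip check uses 10-s trials: on 2-s epochs the
  occupancy of a 4-state chain is too imbalanced for *any* per-trial
  clustering to recover all four maps in ≥99% of trials.
* Filters are zero-phase FIR (Hamming window, firwin design) with length
  scaled to the transition width, giving ≥20 dB stopband and ≤1 dB
  passband ripple at any sampling rate; amplitude rejection is strict
  (|value| > 100 μV removes the epoch).
* GFP peaks are strict local maxima; a plateau that is a local maximum
  resolves to its first sample; endpoints are never peaks; an optional
  minimum peak separation thins greedily by height.
* Degenerate inputs are defined, not silent: GEV of an all-zero epoch,
  features of an all-UNASSIGNED sequence, a Wilcoxon test with all-zero
  differences, and a t-test with constant nonzero differences raise
  typed errors; a t-test of identical samples returns t = 0, p = 1.

## Known limitations

* No bad-channel detection/interpolation and no ICA/PCA artifact removal;
  `preprocess_epochs` exposes an `artifact_hook` where cleaned real data
  can be inserted.
* EDF recordings are read (via MNE); simulated studies are written as
  delimited text matrices plus a manifest rather than EDF.
* The statistics stage assumes complete subject × condition tables after
  exclusion; unbalanced designs are out of scope.
* AAHC results depend on input order only through exact cost ties, which
  are broken deterministically but arbitrarily.
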