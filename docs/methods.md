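# Methods

## The prediction model

The package predicts per-residue secondary structure in the three-state
alphabet {H, E, C}. Its model is a feature-engineered discriminative
classifier, not a structural simulation: it assumes that (i) the local
sequence window around a residue, summarized by evolutionary conservation
(PSSM log-odds) and by the central residue's physicochemical character,
carries most of the signal about the residue's conformational state, and
(ii) states occur in physically constrained runs — a helix of fewer than
three residues or a strand of fewer than two is not a real structure, so
such predictions may be rewritten by local consensus.

### Feature encoding

For window size WS (odd, 7–19) the vector for residue *i* is

    [ P(i-h), ..., P(i), ..., P(i+h),  S_iH, S_iE, S_iC, q_i, h_i, m_i ]

with h = (WS−1)/2, each P(·) a 20-long normalized PSSM row, giving
dimension 20·WS + 6. The six scalars describe the central residue only;
the feature counts at every window size (146 at WS=7 up to 386 at WS=19)
force this layout, and the tests assert it.

* **PSSM normalization.** Raw integer log-odds are mapped to [0, 1] by a
  fixed min–max transform with bounds (−10, +10) and clipping. Fixed
  bounds make the train- and test-time transforms identical without any
  dataset statistics; the logistic transform 1/(1+e^(−x)), the other
  convention common in PSSM-based predictors, is available as an option.
  The transform is stored in the trained model so prediction on new data
  reuses it exactly.
* **Edge padding.** Window positions beyond the chain ends contribute
  all-zero PSSM blocks — zero is "no information" on the min–max scale.
  Half-value (0.5) padding is a parameter for comparison.
* **Conformation parameters.** S_ij = a_ij / a_i, the fraction of
  occurrences of amino acid *i* found in state *j*, estimated by pooling
  counts over the *training* chains only (no test-label leakage); an
  amino acid absent from the training data gets a flagged uniform row
  (1/3, 1/3, 1/3). A published whole-benchmark table is shipped for
  comparison and as the simulator's default propensity source.
* **Physicochemical scalars.** Net charge (R, H, K = +1; D, E = −1; else
  0) mapped {−1, 0, +1} → {0, 0.5, 1}; Kyte–Doolittle hydropathy scaled
  over its table range [−4.5, 4.5]; side-chain mass scaled over
  [1.0079, 130.1689] Da. Scaling constants are the table extrema, fixed
  at build time, never data-dependent. Non-standard residue codes
  (B, Z, X, U, O) receive all-zero physicochemical features and uniform
  propensities under the default lenient policy.

### Classifier

One-vs-one decomposition into the three pairwise problems H/E, E/C, C/H,
each an RBF-kernel SVM (scikit-learn's `SVC`, i.e. LIBSVM) with shared
cost C and width γ; defaults C = 2¹, γ = 2⁻⁴, WS = 13, the grid-search
optimum at that window size. Prediction is max-wins voting. The voting
rule leaves ties open, so they are resolved deterministically: first by
training-set class frequency, then by the fixed order C > H > E (coil is
the safest fallback; a spurious C never creates a fake segment).

Hyper-parameter search is exhaustive over C ∈ {2⁰…2⁵} and γ ∈ {2⁻⁶…2⁻¹}
(36 combinations) per window size, scored by mean cross-validated Q3.
Cross-validation folds partition *chains* (seeded shuffle, round-robin),
never residues: window overlap would otherwise leak test information into
training. Accuracy ties prefer the smallest WS, then smallest C, then
smallest γ — the cheapest model among equals.

### Consensus filter

One pass over the predicted string with frozen-copy semantics: every rule
reads the original prediction and writes to a fresh output, so
replacements cannot cascade and the result is independent of scan order
(an in-place sequential mode exists behind a flag for comparison). For
each position *i* of the original:

* **Case H** — pred[i] = H and not both neighbours H;
* **Case E** — pred[i] = E and neither neighbour E;

in either case pred[i] is replaced by the majority state of positions
[i−3, i+3] clipped to the sequence; a majority tie keeps the original
label (least intervention). Neighbours beyond the ends count as "not
H"/"not E", so terminal singletons are always majority-checked — a
one-residue helix at a chain end is physically implausible. Coil
positions are never examined, hence never changed. The rules do not
literally *guarantee* minimum run lengths and the filter does not iterate
to convergence; both are deliberate.

### Scores

* **Q3** = 100 · (correct residues)/(total residues).
* **SOV99**: for each class, observed segments s1 are paired with every
  overlapping predicted segment s2 and contribute
  ((minov + δ)/maxov)·len(s1) with
  δ = min(maxov−minov, minov, ⌊len(s1)/2⌋, ⌊len(s2)/2⌋) (integer floor,
  clamped ≥ 0); the normalizer counts len(s1) once per pair plus once per
  observed segment with no partner, pooled over the three classes.
* **SOV94**: the earlier definition — δ = min(maxov−minov, minov),
  per-class normalization by the number of observed residues of that
  class, macro-averaged over the classes present in the reference. The
  raw 1994 sum can exceed its normalizer when one observed segment
  overlaps several predictions, so per-class values are capped at 100 to
  keep the score in [0, 100].

Both variants are verified against independent brute-force oracles that
enumerate all segment pairs and apply the formulas literally (agreement to
1e−9 on 1,000 random pairs). Multi-chain evaluation pools confusion
counts and SOV sums before normalizing. Undefined precision/recall
denominators yield NaN, never 0. Scores keep full precision internally;
display rounds to two decimals.

## The synthetic-data generator

`sspipe.simulate` provides the study conditions for every desk-scale
experiment. Defaults: 200 chains, lengths uniform on [30, 80] (short
enough that a full simulate→train→evaluate cycle takes well under a
minute on one CPU; chain-length realism is a parameter, not a default),
PSSM signal 0.8, seed-deterministic throughout.

* **Structure**: first-segment class ~ (H 0.35, E 0.20, C 0.45); run
  lengths geometric with hard floors (H ≥ 3, E ≥ 2, C ≥ 1) and
  continuation parameters giving mean runs of roughly 6/3.5/4 residues;
  between-segment transitions favour returning to coil. A truncated final
  segment that would violate its floor instead extends the previous run,
  so the floors hold in every output.
* **Residues**: emitted from class-conditional distributions obtained by
  Bayes-inverting the shipped propensity table under a uniform residue
  prior, sharpened by a concentration exponent (default 2.5). The
  exponent is the difficulty knob: at 1.0 the class signatures are as
  weak as real single-residue propensities and the trained model barely
  clears the baseline; 2.5 places held-out Q3 in the discriminative
  65–90 % band where regressions are visible without saturating.
* **Profiles**: background scores are discretized Gaussians (mean −2,
  sd 2, clipped to ±10); with probability `pssm_signal` a position is
  "conserved" and its true residue's column is raised strictly above the
  row maximum. At signal 1 the residue is recoverable from every row; at
  signal 0 profiles carry no sequence information (checked by a
  chi-square test).

What passing on this generator shows: the pipeline wiring, feature
layout, leakage-free CV, filter semantics and scoring are correct, and
the classifier extracts a large real margin (≈ +26 Q3 points over the
majority baseline at default settings). What it does not show: accuracy
on real proteins — synthetic chains lack homology structure, long-range
interactions driving sheet formation (the hardest class on real data),
amphipathic periodicity, and realistic PSSM column correlations, so
absolute synthetic scores are not comparable to CB513-style benchmarks.
Reproducing real-benchmark numbers requires PSI-BLAST profiles against
nr (multi-gigabyte, many CPU-hours) and is deliberately out of scope; the
`gridsearch`/`train` CLI accepts real PSI-BLAST ASCII PSSMs unchanged
when such profiles are available.

## Numerical and design notes

* All randomness flows through `numpy.random.default_rng` seeds carried in
  the specs; repeated runs are byte-identical.
* The parameter-recovery check compares the recomputed propensity table
  with the posterior implied by the generator's emission matrix and
  empirical class marginals; the sample (~165k residues) is sized so the
  0.02 acceptance envelope is at least a 3σ binomial bound for the rarest
  amino acid, making the test stable across seeds rather than a coin
  flip.
* Grid-search accuracy is residue-level Q3 (the natural reading of
  benchmark "accuracy" columns); whether historical tables used another
  statistic cannot be determined from their layout.
* Model files are joblib bundles with a format version; they embed the
  encoder (conformation table, window size), the normalization spec and
  the three binary SVMs, so `predict` is self-contained.
* Empty predictions, single-residue chains (all-padding windows),
  zero-count propensity rows and chains shorter than the window are all
  defined cases with tests; degenerate SOV inputs (no segments) score 100
  by convention since nothing is mispredicted.

## Known limitations

* The SOV94 macro-combination over classes follows the per-class
  published definition; other implementations pool classes before
  normalizing, which can differ by a few points on unbalanced data.
* The filter is a single pass; pathological inputs can still contain
  sub-minimum runs afterwards.
* Grid search retrains 36 SVMs per window size per fold; on large real
  datasets this is hours of CPU (as in the original protocol) — use the
  restricted `--ws` option for exploratory runs.
* `SVC` training is O(n²)–O(n³) in residues; tens of thousands of
  training residues are practical, CB513-scale (~84k) requires patience
  or subsampling.
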