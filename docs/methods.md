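# Methods

This note documents the models, parameter defaults, numerical conventions
and design choices behind `ppiface`, and what the synthetic benchmark
does and does not demonstrate.

## Problem and labels

A residue is an interface residue when its accessible surface area
decreases by strictly more than 1 Å² between the unbound and bound forms
of its chain (ΔASA > 1 Å²). ΔASA values are *inputs* here — computing
them from 3-D structures is out of scope — and the label column of the
input table, when absent, is derived from ΔASA by this strict rule.
Negative ΔASA values are rejected.

## Integrative profile

For residue *i* with sequence profile SP<sub>i</sub> (20 non-negative
alignment frequencies in the canonical order `ARNDCQEGHILKMFPSTWYV`) and
the Kyte–Doolittle scale KD over the same order, the per-residue value is
the unbiased (n−1 = 19 divisor) standard deviation of the elementwise
product SP<sub>i</sub>·KD. Two ablation encodings share the windowing:

- `profile_only`: the standard deviation of SP<sub>i</sub> alone.
- `hydropathy_only`: the residue's own KD value. (Literally deleting the
  profile term from the product statistic would leave the standard
  deviation of the fixed KD vector — a residue-independent constant — so
  the mode instead uses the classic per-residue hydropathy value, which
  depends only on amino-acid identity.)

Profiles may be supplied as fractions (default) or HSSP-style
percentages; `profile_scale="percent"` divides by 100 on input. The
statistic is scale-covariant, so the choice only fixes units. The 20
standard amino acids are required; non-standard codes (B, Z, X, U, …)
receive hydropathy 0 with a warning.

## Sliding window

Window length L is odd (default 19; 5, 11, 15, 19, 27 are the
conventional grid, any odd value works). Influence coefficients are a
normal density over slot positions 1…L, centred at μ = (L+1)/2, with
variance the sample variance of the slot positions about μ:
σ² = Σ(i−μ)²/(L−1). The divisor is configurable
(`variance_divisor="population"` uses L) because either convention is
defensible; the default is the unbiased one. The density is used as-is,
without renormalizing the coefficients to sum to 1 — the SVM standardizes
features per member, so a global rescale of a feature column is
absorbed. L = 1 is a degenerate single-slot window; its variance is
fixed at 1. Window slots beyond the chain termini contribute 0 (neutral
padding).

## Balanced subset partition

Training positives are sorted ascending by ΔASA and cut into M contiguous
near-equal blocks (default M = 2); negatives are listed as seed-shuffled
ΔASA = 0 samples followed by the few 0 < ΔASA ≤ 1 samples in ascending
order, and cut into N blocks (default N = 5), giving K = M×N = 10
members. Keeping the sub-threshold negatives at the tail preserves the
ΔASA ordering information; when a class size is not divisible by the
subset count, earlier subsets take the extra sample. A fully random
partition (`strategy="random"`) is available as the baseline comparison.

## SVM ensemble and voting

Each member is an RBF-kernel SVC (C = 1, γ = 1/L) preceded by a
`StandardScaler` fitted on that member's own training pair; all
hyperparameters are exposed in `SVMConfig`. Members emit hard 0/1 votes
(decision values can be stored for diagnostics but never enter the
combination), and the ensemble calls a residue positive when at least TH
of K votes are positive. The threshold sweep reports all six measures for
TH = 1…K and marks the best-MCC and best-F1 rows; selection of an
operating TH is left to the user, since picking it on test data is an
optimistic convention.

## Modified SOM filter

The SOM is an N×N grid in a hexagonal layer (odd rows offset by half a
unit, rows sqrt(3)/2 apart) trained by deterministic *batch* updates:
each of the 20 default steps assigns every sample to its best-matching
neuron and moves each weight to the Gaussian-neighbourhood-weighted mean
of the data, with the radius decaying linearly from N/2 to 0.5. Batch
training was chosen over online Kohonen updates because it has no
learning-rate schedule to guess, is what the classic MATLAB-era SOM
tooling uses, and is exactly reproducible from the initialization seed
(weights start as a seeded sample of training points). Weights therefore
always remain inside the convex hull of the data.

Hard assignment makes the entropy index degenerate (every column crisp,
E ≡ 0), so memberships are softened:
U<sub>rn</sub> ∝ exp(−‖x<sub>n</sub>−w<sub>r</sub>‖²/(2τ²)) normalized
over neurons, with τ the median nearest-neighbour distance between
weights (τ → 0 recovers crisp assignment; duplicate weights fall back to
a tiny ε). The validation index is the Shannon form
E = −(1/n) Σ<sub>n</sub> Σ<sub>r</sub> U<sub>rn</sub> ln U<sub>rn</sub>
(natural log), bounded by [0, ln R]: 0 means perfectly distinct clusters,
ln R no structure. Per-neuron contributions average the column entropies
of the samples hard-assigned to each neuron.

Pruning applies two rules in order: neurons with fewer than
`min_count` = max(2, 1% of n/R) samples are removed, then neurons whose
per-neuron entropy exceeds the median of the survivors (a float cutoff or
`None` disables the rule). Selection happens once per CV fold on the
training assignment; test samples mapping to removed neurons are excluded
from evaluation as well, matching the convention that retained clusters
define the operating domain of the filtered model. With `min_count=0` and
the entropy rule disabled the filter is the identity and the pipeline is
bit-for-bit equal to the unfiltered one (this is a tested invariant).

## Cross-validation and reporting

Folds are assigned at the chain level (default k = 5, near-equal chain
counts); every chain is tested exactly once. Fold metrics are pooled by
concatenating votes and labels across folds (micro-average), matching the
convention of reporting single dataset-wide measures; per-fold sweeps are
also emitted. Degenerate metric denominators yield 0 with a
`defined=False` flag, never NaN; a zero MCC denominator maps to MCC = 0
(the random-guess interpretation). Amino-acid propensities are
log₂(freq(a|interface)/freq(a|non-interface)) with within-class
normalization; zero counts use add-one smoothing and are flagged.

Every per-stage seed (CV shuffle, per-fold partition shuffle, per-fold
SOM init) is derived from the single run seed by hashing stage tags, so
adding or removing the SOM stage does not perturb the other stages'
randomness, and a manifest (config, seed, SHA-256 of the inputs, package
version) reproduces any run exactly.

## Synthetic benchmark

The generator emulates the *shape* of real inputs, not their content:

- interface residues form contiguous sequence patches (geometric lengths,
  mean 6), reflecting the spatial clustering of real interfaces that the
  windowed features presume; patches may hang off chain ends and
  overshoot is trimmed from the last-placed patch, so positive coverage
  is positionally unbiased — with no planted signal, chain-terminus
  window padding must not become a class cue;
- per-residue profiles are Dirichlet draws with base concentration 1 plus
  a class tilt scaled by `signal_strength`: interface residues toward the
  hydrophilic, high-|KD| amino acids R (weight 3), H (1.5), W, Y (0.75
  each); non-interface residues toward the hydrophobic, low-|KD| G (3),
  A (2), V (1). Concentrating the positive tilt on high-|KD| and the
  negative tilt on low-|KD| amino acids plants the signal in the
  profile–hydropathy *interaction*, so the integrative statistic
  separates the classes while the profile-only standard deviation barely
  does;
- residue identities are drawn with the same tilts at half strength, so
  interface regions are mildly enriched in R/Y/W/H (the propensity
  analysis recovers this) and the hydropathy-only channel is weakly but
  not competitively informative;
- positive ΔASA is 1 + Exponential(mean dasa_max/3) Å² (default
  dasa_max = 100); negatives are 90% exactly 0 with the rest uniform in
  (0, 1]. Labels equal the ΔASA rule by construction;
- defaults: 40 chains of 100–200 residues, interface fraction 0.2756.

Passing the benchmark therefore shows that the pipeline recovers a
planted interaction signal with the expected orderings (ensemble ≥ best
member; integrative > either ablation; no skill at zero signal). It does
*not* show performance on real proteins: real profiles have position
dependence, phylogenetic correlation and alignment-depth artifacts, and
real ΔASA distributions are not exponential.

The null-signal control evaluates the pooled MCC at the fixed majority
threshold (TH = ⌈K/2⌉) rather than the best-over-TH value, because
maximizing over thresholds is positively biased even under a true null;
and it averages three generator seeds because the patch structure of the
labels inflates the per-seed sampling variance of MCC (measured sd ≈ 0.03
at ~6,000 residues) well beyond the i.i.d. value.

## Problem sizes

Library tests run on 10–12 chains of 40–60 residues; the benchmark used
by the acceptance checks and `scripts/acceptance.py` uses the default
40-chain fixture (~6,000 residues), chosen as the smallest size at which
the pooled MCC estimates are stable across seeds.

## Known limitations

- The SOM filter changes the evaluated sample set, so filtered and
  unfiltered MCCs compare models on different residue subsets — exactly
  as the retained-cluster reporting convention implies, but worth
  remembering when reading the tables.
- `hydropathy_only` is a windowed amino-acid property, not a learned
  profile; it exists for ablation, not as a serious predictor.
- Propensity smoothing (add-one) biases extreme log-ratios toward 0 for
  rare amino acids; flagged rows should not be over-interpreted.
- The ensemble trains M×N SVMs per fold; for very large datasets the
  quadratic kernel-matrix cost dominates and a linear kernel (exposed in
  `SVMConfig`) may be preferable.
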