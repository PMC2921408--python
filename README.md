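# ppiface

Sequence-based prediction of protein–protein **interface residues**: the
residues of a protein chain whose solvent-accessible surface area (ASA)
drops by more than 1 Å² when the chain binds its partner. Because solved
complex structures are scarce relative to sequences, predicting these
residues from sequence-derived information alone is a long-standing
problem in structural bioinformatics; `ppiface` is aimed at computational
biologists who want a small, fast, fully reproducible predictor and
evaluation harness for it.

## The method

Each residue *i* carries a 20-value evolutionary **sequence profile**
*SP<sub>i</sub>* (amino-acid frequencies from a multiple alignment,
HSSP-style) and the fixed **Kyte–Doolittle hydropathy scale** *KD* over
the same canonical amino-acid ordering `ARNDCQEGHILKMFPSTWYV`. The core
per-residue statistic is the *integrative profile*,

```
SD_i = sqrt( Σ_k ( SP_ik · KD_k − mean(SP_i · KD) )² / 19 ),
```

the unbiased standard deviation of the elementwise profile × hydropathy
product — a scalar measuring how strongly the residue's evolutionary
context fluctuates with respect to hydrophobicity. A sliding window of
odd length *L* (default 19) centred on residue *i* turns this into a
1 × *L* feature vector

```
V_i = ( SD_{i−(L−1)/2} · p_1 , … , SD_{i+(L−1)/2} · p_L ),
```

where the influence coefficients *p<sub>j</sub>* are a normal density
centred at the window midpoint μ = (L+1)/2 with variance
σ² = Σ<sub>j</sub>(j−μ)²/(L−1); window slots outside the chain contribute 0.

Because only ~28% of residues are interface residues, training data are
split into *M* positive and *N* negative non-overlapping subsets of
near-equal size, ordered by ΔASA (negatives with ΔASA ≡ 0 are shuffled).
One RBF-kernel SVM is trained per subset pair — *M*×*N* = 10 balanced
members by default — and a residue is called an interface residue when at
least *TH* members vote positive, for *TH* swept over 1…*K*. Optionally a
modified self-organizing map (hexagonal *N*×*N* grid, batch-trained for
20 steps) gates the samples first: neurons with few samples or with a
large entropy-index contribution are pruned, and only residues mapping to
retained clusters are trained/tested on. Performance is reported with six
measures: sensitivity, specificity, accuracy, precision, F1 and the
Matthews correlation coefficient (MCC).

Everything runs on synthetic data shipped with the package: a seeded
generator produces chains with patch-structured interfaces, Dirichlet
profiles whose class signal lives in the profile–hydropathy interaction,
and ΔASA values consistent with the labelling rule, so no external
databases (HSSP, PSAIA output) are needed to build, test or benchmark.

## Worked example

The tiny documented chain `GRAVY` (uniform profile on G; profile mass
0.62/0.81/0.43/0.24 on the residue's own amino acid for R/A/V/Y):

```python
>>> from ppiface import (worked_example_chain, KYTE_DOOLITTLE,
...                      gaussian_coefficients, integrative_sd, encode_chain)
>>> chain = worked_example_chain()
>>> kd = KYTE_DOOLITTLE.vector()
>>> [round(integrative_sd(r.sp, kd), 4) for r in chain.residues]
[0.1493, 0.6252, 0.3287, 0.4172, 0.1362]
>>> coeffs = gaussian_coefficients(3)        # mu=2, sigma2=1
>>> encode_chain(chain, coeffs)[2].v.round(4)  # window around the central A
array([0.1513, 0.1311, 0.1009])
```

The SD values peak at arginine (R): its profile concentrates mass on the
most hydrophilic amino acid (KD −4.5), giving a large product fluctuation.
The central residue's feature vector is its neighbours' SD values scaled
by the Gaussian coefficients (0.2420, 0.3989, 0.2420).

A full command-line run on synthetic data:

```
ppiface simulate --n-chains 40 --seed 1 --out fixture/
ppiface cv --fasta fixture/chains.fasta --profiles fixture/profiles.tsv \
           --labels fixture/labels.tsv --seed 1 --out cv_out/
pooled best MCC 0.6750 at TH=6 (F1 76.87%); reports in cv_out/
```

`cv_out/pooled_sweep.tsv` holds the six measures for every threshold,
`member_metrics.tsv` the per-SVM results (best individual member MCC
0.6635 here — the threshold vote beats every single member), and
`manifest.json` the config, seed and input hashes that make the run
exactly reproducible.

## Layout

- `ppiface.profile_features` — hydropathy scale, window coefficients, encodings
- `ppiface.dataset` — ΔASA labelling, balanced partitions, chain-level CV folds
- `ppiface.som_filter` — batch hexagonal SOM, entropy index, cluster pruning
- `ppiface.svm_ensemble` — member training, vote combination, threshold sweep
- `ppiface.evaluation` — six-measure metrics, propensities, curve tables
- `ppiface.synthetic` — seeded fixture generator and the worked example
- `ppiface.pipeline` / `ppiface.cli` — cross-validated runs, manifests, CLI

See `docs/methods.md` for the modelling assumptions, parameter defaults
and numerical conventions.
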