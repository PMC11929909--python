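# qpop

Analysis pipeline for ex vivo combinatorial drug-sensitivity screens
of the QPOP (quadratic phenotypic optimization platform) family, as
used in functional precision oncology: a patient-derived sample is
exposed to a small, carefully designed array of drug-dose combinations,
and a second-order regression of the phenotypic readout ranks *all*
possible drug-dose therapies from a 12-drug panel — far more than were
ever tested.

It is a library for computational scientists working with such
screens. It provides:

* **Design** — the 155-run orthogonal array composite design (OACD)
  for 12 three-level factors: a resolution-IV 2^(12-5) fractional
  factorial (128 runs, coded levels {0, 2}) plus the L27(3^13)
  orthogonal array (27 runs, levels {0, 1, 2}), with estimability
  validation and dose mapping against a drug panel (IC0/IC10/IC20).
* **Plate QC** — normalization of raw CellTiter-Glo-style luminescence
  to normalized cell viability (NCV) against on-plate controls, and
  assay gating on the Z'-factor with SSMD reported alongside.
* **Model and ranking** — OLS fit of the 91-term quadratic
  NCV(x) = b0 + Σ b_i x_i + Σ b_ii x_i² + Σ b_ij x_i x_j on coded
  levels, enumeration of every 1-3-drug therapy over its nonzero dose
  permutations, ranking by mean NCV (rank 1 = strongest predicted
  kill), response-surface maps per drug pair, and per-sample JSON
  reports.
* **Dose-response** — four-parameter-logistic IC50 fitting with
  multi-start initialization, closed-form IC10/IC20 inversion, and
  median-effect fits.
* **Synergy** — Chou-Talalay combination index curves at constant dose
  ratio (CI < 1 synergy) and Bliss independence excess scoring of 5x5
  dose matrices (score > 10 synergistic, < −10 antagonistic).
* **Clinical concordance** — ROC/AUC of therapy mean NCV against
  RECIST response with a Youden-J NCV cutoff, responder 2x2 analysis
  (odds ratio, exact Fisher p, total predictive value), cohort-level
  top-combination frequencies, one- vs two-drug correlations, and the
  xenograft volume/growth-rate formulas.
* **Synthetic data** — a generator producing ground-truth quadratic
  surfaces with planted synergistic pairs, noisy control-anchored
  plates, dose-response tables and outcome-linked cohorts, so every
  stage has parameter-recovery tests without access to raw screen
  data.

## Worked example

```python
import qpop

design = qpop.build_oacd(12)                 # 155 runs, rank-91 basis
panel  = qpop.default_panel()

truth  = qpop.gen_ground_truth(12, planted_pairs=[(8, 10)],
                               effect_scale=0.2, noise_sd=0.02, seed=1)
plate  = qpop.simulate_plate(truth, design, seed=2)   # duplicates + controls
model  = qpop.fit_quadratic(qpop.normalize(plate), design)
top    = qpop.rank_combinations(model, order=2).top(3)
```

Running `python examples/design_and_ranking.py` (which does exactly
this) prints:

```
design: 155 runs (128 factorial + 27 orthogonal-array), quadratic basis rank 91/91
fit: R^2 = 0.9978 on 310 replicate wells

top 5 two-drug therapies (lower mean NCV = greater predicted kill):
  rank  1  AZD5153 + pazopanib          mean NCV 0.542 +/- 0.270
  rank  2  doxorubicin + eribulin       mean NCV 0.936 +/- 0.006
  rank  3  ifosfamide + doxorubicin     mean NCV 0.954 +/- 0.003
  ...
```

The mean NCV of a therapy averages the model's predictions over its
nonzero dose permutations (4 for a pair); 0.542 means the model
expects the pair to leave 54% of cells viable on average across its
tested dose combinations — the planted synergistic pair, recovered at
rank 1 from a noisy simulated screen. The other `examples/` scripts
walk through plate QC, IC50 fitting, synergy validation and
outcome-concordance analysis the same way.

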