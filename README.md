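# dmnstab

Within- and between-subject stability of directed (effective) connectivity
in the core default mode network (DMN), as a fully tested, simulation-backed
pipeline.

## The problem

Resting-state fMRI studies of the DMN usually report group-average directed
connectivity among four regions — precuneus (PRC), medial prefrontal cortex
(mPFC) and left/right inferior parietal cortex (lIPC, rIPC). Whether a
*single subject's* directed connectivity pattern is reproducible across many
scan sessions, and what drives the differences between subjects, is a
different question, and it matters for any clinical use of such estimates.
The dominant source of between-subject variability turns out to be
hemispheric asymmetry: most subjects have one out-degree-dominant IPC, and
once matrices are re-ordered from a left/right to a dominant/non-dominant
convention, subjects look strikingly alike.

`dmnstab` implements that analysis end to end on synthetic longitudinal
cohorts:

- **`cohort`** — a hierarchical generator (group → subject → session) of
  4×4 effective-connectivity matrices with a configurable lateralization
  effect, plus Gaussian session "posteriors" and a diffable on-disk format;
- **`spectral`** — a linear stochastic model `dx/dt = A x + v` with
  power-law fluctuation spectra and a linearized Balloon hemodynamic
  transfer; cross-spectral prediction `S(f) = T G_v T* + G_e`, time-series
  synthesis, Welch estimation, and MAP inversion with a Laplace posterior;
- **`hierarchy`** — parametric-empirical-Bayes averaging of Gaussian
  posteriors over sessions and subjects (per-parameter random-effects
  variances, EM), and closed-form Bayesian model reduction (BMR) for
  empirical priors;
- **`stability`** — the asymmetry index (mean lIPC efferent − mean rIPC
  efferent, in Hz, with a 90% posterior-probability criterion), dominance
  reordering, pairwise matrix correlations, sign-stability tables, and a
  PCA rule for asymmetric loading patterns;
- **`inference`** — exact two-sided binomial tests of dominance stability,
  Benjamini–Hochberg FDR control, pairwise swap-randomization nulls for the
  consistency gain, and paired label-randomization tests;
- **`qc`** — framewise displacement, Gaussian KL effective-parameter
  counts, principal eigenvariates, the stepwise alpha rule, and the
  five-criterion session gate (explained variance > 60%, a connection
  > 1/8 Hz, ≥ 1 effective parameter, max FD < 1.5 mm, voxel detection at
  alpha ≤ 0.05).

Conventions: `A[target, source]` (column → row influence, Hz); diagonal
entries are unitless log-scale parameters `a` with effective
self-connection `−0.5·exp(a)` Hz, so self-influence is always inhibitory.

## Worked example

Recompute the per-subject stability table from the printed session counts,
then run the dominance-reordering analysis on a synthetic 16-subject cohort:

```python
import numpy as np
import dmnstab as d
from dmnstab.stability import asymmetry, pairwise_consistency, dominance_reorder
from dmnstab.inference import published_stability_table, swap_null_between

cols = ["subject_id", "n_asymmetric_sessions", "effect_size_pct",
        "p_uncorrected", "p_fdr"]
print(published_stability_table()[cols].head(4)
      .to_string(index=False, float_format=lambda x: f"{x:.3f}"))

spec = d.CohortSpec(seed=1)                       # 16 subjects x 10 sessions
truth = d.sample_cohort(spec)
posts = d.emit_session_posteriors(truth)
by = {}
for p in posts:
    by.setdefault(p.subject_id, []).append(p)
subs = [d.peb_average(v).group_posterior for v in by.values()]

doms = [asymmetry(s).dominance for s in subs]
_, before = pairwise_consistency(subs)
reordered = [dominance_reorder(s, dm) for s, dm in zip(subs, doms) if dm != "none"]
_, after = pairwise_consistency(reordered)
res = swap_null_between(np.stack([s.mean for s in subs]), n_rand=5000, seed=2)
print(f"mean pairwise correlation: {before:.2f} -> {after:.2f}")
print(f"swap-randomization: effect = {res.observed_effect:.3f}, p = {res.p_value:.4f}")
```

prints

```
subject_id  n_asymmetric_sessions  effect_size_pct  p_uncorrected  p_fdr
        S1                     74           71.600          0.000  0.001
        S2                    135           74.800          0.000  0.000
        S3                     48           87.500          0.000  0.000
        S4                     12           66.600          0.388  0.443
mean pairwise correlation: 0.70 -> 0.90
swap-randomization: effect = 0.200, p = 0.0002
```

The first block is the exact binomial / FDR analysis of how often each
subject's sessions share the subject's dominant hemisphere (S1: 74
asymmetric sessions, 71.6% matching, significant after FDR; S4: only 12
sessions, not significant). The second block shows the headline phenomenon:
between-subject similarity of connectivity jumps once each subject's
dominant IPC is mapped to a common slot, and a pairwise swap-randomization
null (efferent connections of the two IPCs exchanged per subject with
probability ½, dominance re-derived, matrices re-ordered) shows the gain is
far larger than relabelling noise could produce.

A thin CLI covers the pipeline stages:

```
dmnstab simulate --config cohort.yaml --out DIR --seed 1
dmnstab peb --in DIR --level group --out group.json
dmnstab stability --in DIR --criterion 0.9 --out report.json
dmnstab randomize --in DIR --mode between --nrand 5000 --seed 1 --out rand.json
dmnstab table2 --out stability_table.tsv
```

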