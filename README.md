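# flywalk

Hierarchical hidden Markov modelling of fruit-fly locomotion and its
modulation by odors.

A walking fly in a small circular arena does not move randomly: it
strings together recognizable *locomotor features* — stops, slow
meanders, sharp turns, straight medium-speed runs, fast curved runs —
each lasting from a fraction of a second to several seconds.  `flywalk`
decomposes centroid trajectories into such features with a two-level
hierarchical hidden Markov model (HHMM) and quantifies how an odor
delivered in the arena's center shifts the time a fly spends in each
feature, at the level of the whole cohort, of clusters of flies, and of
individual flies.  It is aimed at researchers analyzing arena-walking
assays who want a generative, probabilistic alternative to ad-hoc
speed/turn thresholds.

## The model

Trajectories sampled at 30 frames/s are reduced to two observables per
frame: the components of the displacement parallel (v∥) and
perpendicular (v⊥) to the previous frame's displacement.  Straight
motion gives v⊥ = 0; counterclockwise (left) turns give v⊥ < 0; speed
and path curvature are recoverable as √(v∥² + v⊥²) and
v⊥/|d<sub>t−1</sub>|².

The generative model is a two-level hierarchy.  Each of N<sub>HL</sub>
high-level (HL) states — the locomotor features — owns N<sub>LL</sub>
low-level (LL) states carrying bivariate Gaussian emissions on
(v∥, v⊥).  Within an HL state the LL chain evolves by that state's
transition matrix A<sub>k</sub>; each LL row also holds a terminal
(exit) probability by which control returns to the HL chain Q, and the
destination HL state re-enters through its initial LL distribution.
A two-level model with 10 HL × 5 LL states has
10² + 10·5² + 50·5 = 600 free parameters, far fewer than the
50² + 50·5 = 2750 of a flat 50-state HMM.

Fitting is by variational Bayesian EM with conjugate priors: Dirichlet
rows on all transition and initial distributions (sparse, favoring
self-transitions 6:1 with a total strength of two observations) and
Normal-inverse-Wishart emissions.  The E-step runs scaled
forward-backward over the flattened joint chain using the
exponentiated geometric-mean parameters exp E[log A]; the evidence
lower bound (ELBO) is non-decreasing and is also the model-comparison
currency: P(HHMM|O) = 1/(1 + e<sup>−log K</sup>) with log K the ELBO
difference against a matched flat HMM.

Downstream analyses mirror a complete ethological workflow: MAP state
sequences filtered at 0.85 posterior confidence and despiked (<5-frame
flickers, 1-frame dwells); states ordered by mean speed / curvature
variance; per-fly occupancy vectors over HL states in four scenarios
(inside/outside the odor zone × before/after first entry); BCa
bootstrap confidence intervals and a bootstrap equal-means test with
Holm–Bonferroni correction; X-means clustering of flies with a
flat-Dirichlet simplex null; logistic-regression decoding of odor
presence from 1-s state-usage bins; and a synthetic-data module that
generates full arena cohorts with known ground truth.

## Worked example

Simulate a small cohort, fit a model, and measure the odor effect:

```python
import numpy as np
from flywalk.synthetic_data import CohortConfig, synthesize_cohort
from flywalk.hhmm import HHMMSpec
from flywalk.pipeline import analyze_cohort
from flywalk.odor_stats import equal_means_table

config = CohortConfig(seed=7)          # 34 flies, 6 min at 30 Hz, 4 types
cohort = synthesize_cohort(config)
res = analyze_cohort([f.rec for f in cohort], HHMMSpec(n_hl=6, n_ll=3),
                     seed=1)
print("clusters found:", res.clusters.k)
print("median fraction of confidently assigned frames:",
      round(np.median(res.assigned_fraction), 3))
bi, di = res.occupancy["B_I"], res.occupancy["D_I"]
ok = ~(np.isnan(bi).any(axis=1) | np.isnan(di).any(axis=1))
print(equal_means_table(bi[ok], di[ok], n_boot=5000, seed=2))
```

Output (about five minutes on one core):

```
clusters found: 4
median fraction of confidently assigned frames: 0.831
   hl   p_value  significant_holm_05  significant_uncorrected_01
0   1  0.000200                 True                        True
1   2  0.007798                 True                        True
2   3  0.011998                 True                       False
3   4  0.026195                 True                       False
4   5  0.003799                 True                        True
5   6  0.000400                 True                        True
```

States are ordered from slow/turning to fast/straight by mean speed
over curvature variance, so states 1–2 are the slowest fitted
features.  Their occupancy inside the odor zone rises after odor onset
— the configured "local search" response of the simulated flies —
while the fast states lose the corresponding share, and the
reallocation is significant across the board.  The cluster count
recovers the four planted locomotor types exactly.

A thin CLI covers the shell-friendly stages:

```bash
flywalk simulate --preset arena34 --seed 1 --out cohort/
flywalk fit cohort-observables/*.csv --n-hl 10 --n-ll 5 --out model.npz
flywalk compare --model-a hhmm.npz --model-b hmm.npz
```

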