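# qfasa

Quantitative fatty acid signature analysis (QFASA) in Python: estimating
the diet composition of lipid-rich consumers — polar bears, seals, seabirds
— from the fatty-acid profiles of their adipose tissue.

## The problem and the model

A fatty acid signature (FAS) is a compositional vector `x` of proportions,
one per fatty acid, summing to 1. Because many dietary fatty acids are
deposited in predator tissue with limited modification, a predator's
signature carries information about what it ate. QFASA models the predator
signature as a mixture of prey-type mean signatures and reads the mixing
weights as diet proportions:

```
pi_hat = argmin_{pi >= 0, sum(pi) = 1}  D( x , sum_k pi_k mu_k )
```

where `mu_k` is the mean signature of prey group `k` and `D` is either the
symmetrized Kullback–Leibler distance `sum_i (x_i - y_i) ln(x_i / y_i)` or
the Aitchison distance (Euclidean distance between centered log-ratio
transforms). Predator metabolism is handled by per-fatty-acid
multiplicative *calibration coefficients* (CCs) `c`: either the predator
signature is divided by `c` and renormalized before fitting ("prey
space"), or each prey mean is multiplied by `c` and renormalized
("predator space").

Three method presets bundle the established option combinations:

| preset | model | space | distance | completion | fatty acids |
|---|---|---|---|---|---|
| `method1` | fixed CCs | prey | Kullback–Leibler | normalize | 31 |
| `method2` | fixed CCs | predator | Aitchison | augment | 30 |
| `method3` | joint (CCs estimated) | predator | Aitchison | augment | 31 |

`method3` is the CC-unconditional model: a single shared CC vector is
estimated *simultaneously* with all predators' diets by minimizing the
summed Aitchison distance under the identifiability constraint
`sum(c) = K` (mean coefficient 1), removing the dependence on
feeding-trial CC values.

The package also implements the supporting machinery: zero replacement and
multiplicative normalization, signature augmentation, distance-based
permutation ANOVA (pseudo-F with exact enumeration or sampled
permutations) for deciding prey-group structure, and diagnostics —
leave-one-prey-out (LOPO) cross-validation, the proportion of predator
proportions outside the prey-mean range, the within-group distance share
`psi`, per-predator fit distances, and cross-method Pearson correlations.
A synthetic-data generator produces prey libraries, CC vectors and
pseudo-predators with known truth so every stage is testable end to end.

## Worked example

```python
import numpy as np
import qfasa as q

spec = q.SimulationSpec(G=4, K=12, n_per_group=10, n_predators=20,
                        noise_spread=0.02, cc_spread=0.2, seed=42)
library = q.simulate_prey_library(spec)
cc_true = q.simulate_cc(spec)
predators, truth = q.simulate_predators(library, cc_true, spec)

# fixed-CC estimation (predator space, Aitchison distance)
config = q.MethodConfig("fixed_cc", "predator", "aitchison",
                        "normalize", library.signatures.fa_names)
diets = q.estimate_all(predators, library, cc_true, config)
print("first predator diet:", np.round(diets.pi_matrix[0], 3))
print("true diet:          ", np.round(truth.true_diets[0], 3))

# prey-library diagnostics
print("psi:", round(q.psi(library, "aitchison").psi, 4))
means = q.prey_group_means(library)
print("out-of-range:", round(q.out_of_range_proportion(
    predators, means, cc_true, config), 4))

# joint estimation of diets and calibration coefficients
fit = q.estimate_joint(predators, library, seed=0, n_starts=2)
report = q.recovery_report(truth, fit.diets, fit.c_hat)
print("CC max relative error:", round(report["cc_max_relative_error"], 4))
print("diet mean RMSE:", round(report["mean_predator_rmse"], 4))

# are the prey groups really distinct?
dm = q.distance_matrix(library.signatures, "aitchison")
res = q.permanova(dm, library.group_labels, max_reps=999, seed=1)
print("PERMANOVA F:", round(res.f_stat, 2), "p:", res.p_value)
```

Output:

```
first predator diet: [0.745 0.103 0.107 0.045]
true diet:           [0.739 0.102 0.101 0.059]
psi: 0.0757
out-of-range: 0.0
CC max relative error: 0.0133
diet mean RMSE: 0.0139
PERMANOVA F: 126.13 p: 0.001
```

The fixed-CC estimate recovers the simulated diet to within the noise
level; `psi = 0.076` says only 7.6% of the total pairwise prey distance
lies within groups (well-differentiated prey); no predator proportion
falls outside the prey-mean range, so the mixture assumption is tenable;
the joint model recovers the 12 calibration coefficients to within 1.3%;
and the permutation ANOVA confirms group structure (p = 0.001, the
smallest value attainable with 999 sampled permutations).

A command line mirrors the library: `qfasa simulate`, `qfasa estimate`,
`qfasa estimate-joint`, `qfasa diagnostics`, `qfasa permanova`,
`qfasa report` (see `qfasa --help`).

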