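"""Group inference on a simulated cohort: seed maps, maxT correction, follow-ups.

Simulates a reduced cohort, preprocesses every subject, computes the rAI
seed's directed-outflow map, and runs the covariate-adjusted two-sample
contrast with permutation familywise-error correction inside the one-sample
search mask.
"""

import numpy as np

from rsgca import (
    CohortConfig,
    GroupDesign,
    PreprocConfig,
    fwe_correct,
    mask_from_one_sample,
    one_sample_map,
    preprocess_series,
    seed_gca_map,
    simulate_cohort,
    two_sample_map,
)

subjects = simulate_cohort(CohortConfig(n_controls=20, n_patients=20,
                                        n_timepoints=300, rng_seed=3))
pp = PreprocConfig()
rows = []
for s in subjects:
    clean = preprocess_series(s.series, pp, s.confounds, s.confound_names)
    i = s.regions.index("rAI")
    others = [r for r in s.regions if r != "rAI"]
    cols = [s.regions.index(r) for r in others]
    rows.append(seed_gca_map(clean[:, i], clean[:, cols], target_names=others).beta_xy)
values = np.vstack(rows)
targets = [r for r in subjects[0].regions if r != "rAI"]

design = GroupDesign(
    [s.id for s in subjects],
    np.array([1.0 if s.group == "patient" else 0.0 for s in subjects]),
    age=np.array([s.age for s in subjects]),
    gender=np.array([1.0 if s.gender == "F" else 0.0 for s in subjects]),
)

rng = np.random.default_rng(0)
one = one_sample_map(values, targets)
one.p_fwe = fwe_correct(values, "one_sample", n_perm=1000, rng=rng)
mask = mask_from_one_sample(one, alpha=0.05)
two = two_sample_map(values, design, targets)
p_fwe = fwe_correct(values, "two_sample", design=design, n_perm=1000,
                    mask=mask, rng=rng)

print(f"{'target':14s} {'t(two-sample)':>13s} {'p_unc':>8s} {'p_fwe':>8s}  in mask")
for j, t in enumerate(targets):
    pf = f"{p_fwe[j]:.4f}" if np.isfinite(p_fwe[j]) else "   --"
    print(f"{t:14s} {two.t[j]:13.2f} {two.p_unc[j]:8.4f} {pf:>8s}  {mask[j]}")

# Negative t = patients lower. The rDLPFC target carries the planted loss of
# excitatory outflow (control 0.103 vs patient 0.027) and should reach
# familywise significance inside the search mask; targets whose one-sample
# map is null are excluded from the mask and so from the corrected contrast.
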