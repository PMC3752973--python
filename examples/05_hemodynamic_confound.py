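"""The hemodynamic-delay confound, demonstrated by simulation.

Lag-based directed inference on BOLD-like signals can be confounded by
regional differences in hemodynamic delay. This script shows both halves of
the argument: a delay offset that is *consistent across subjects* fabricates
a group-level directed effect from purely instantaneous coupling, while
delays that vary randomly between subjects average out, so a random-effects
group test stays null.
"""

import numpy as np

from rsgca import HemoSpec, apply_hemodynamics, pairwise_gca

rng = np.random.default_rng(0)
hemo = HemoSpec(delay_jitter_sd_s=0.0)


def group_betas(delayer, n_subjects=60):
    betas = []
    for _ in range(n_subjects):
        shared = rng.standard_normal(1600)
        neural = shared[:, None] + 0.3 * rng.standard_normal((1600, 2))
        bold = apply_hemodynamics(neural, hemo, delays_s=delayer())
        betas.append(pairwise_gca(bold[:, 0], bold[:, 1])[0])
    b = np.asarray(betas)
    t = b.mean() / (b.std(ddof=1) / np.sqrt(len(b)))
    return b.mean(), t


m1, t1 = group_betas(lambda: np.array([6.0, 7.0]))
m2, t2 = group_betas(lambda: np.array([6.0, 6.0 + rng.choice([-1.0, 1.0])]))

print("two regions share one signal with ZERO neural lag")
print(f"consistent +1 s delay on region 2: mean beta = {m1:+.4f}, t = {t1:+.1f}")
print(f"subject-random +/-1 s delays:      mean beta = {m2:+.4f}, t = {t2:+.1f}")

# The consistent offset produces a strongly 'significant' spurious directed
# influence; random-sign delays leave the group effect null. A significant
# random-effects result therefore implies a delay (neural or hemodynamic)
# that is systematic across subjects — the basis for interpreting group GCA.
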