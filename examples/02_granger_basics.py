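"""The lag-1 signed path coefficient on a transparent toy system.

Constructs two series where y is driven purely by the lag-1 past of x with
coefficient 0.103 (the control-group value of the emulated study), and shows
that the estimator recovers it while the reverse direction and the zero-lag
correlation stay near zero.
"""

import numpy as np

from rsgca import fc_map, pairwise_gca

rng = np.random.default_rng(0)
c = 0.103
n_subjects, T = 35, 300

bxy, byx, r0 = [], [], []
for _ in range(n_subjects):
    x = rng.standard_normal(T)
    e = np.sqrt(1 - c**2) * rng.standard_normal(T)
    y = np.concatenate([[e[0]], c * x[:-1] + e[1:]])
    f, b = pairwise_gca(x, y)
    bxy.append(f)
    byx.append(b)
    r0.append(fc_map(x, y[:, None]).r[0])

print(f"generating coefficient (x -> y at lag 1): {c}")
print(f"mean estimated beta_xy over {n_subjects} subjects: {np.mean(bxy):+.4f}")
print(f"mean estimated beta_yx (no true y -> x path):      {np.mean(byx):+.4f}")
print(f"mean zero-lag Pearson r (no instantaneous path):   {np.mean(r0):+.4f}")

# beta_xy lands on the generating value; the reverse coefficient and the
# instantaneous correlation hover near zero, which is exactly the
# distinction between directed (lagged) and functional (zero-lag) coupling.
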