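"""Why rounding matters: a hyper-rectangle with sides spanning 7 decades.

Runs plain hit-and-run and LP-rounded hit-and-run at the same step budget on
a D=20 box with sides from 1e-2 to 1e5, then scores each axis marginal
against the exact flat distribution with the Kullback-Leibler divergence
(bits).  Without rounding the walker cannot traverse the long axes, so their
marginals are badly non-flat; with the matching ellipsoid every axis is flat.
"""

import numpy as np

from fluxhr import (
    find_interior_point,
    hr_sample,
    kld_vs_uniform,
    lp_ellipsoid,
    make_hyperrectangle,
)

D = 20
rect = make_hyperrectangle(D)  # sides 1e-2 ... 1e5, geometric
sides = np.logspace(-2, 5, D)
start = find_interior_point(rect, seed=0)
budget, thin = 400_000, 2

plain = hr_sample(rect, start, n=budget // thin, thin=thin, seed=1)
ell = lp_ellipsoid(rect, seed=0)
rounded = hr_sample(rect, start, n=budget // thin, thin=thin,
                    ellipsoid=ell, seed=1)

for name, chain in (("plain HR", plain), ("rounded HR", rounded)):
    kld = [kld_vs_uniform(chain.points[:, j], 0, sides[j]) for j in range(D)]
    print(f"{name:>10s}: max per-axis KLD = {max(kld):8.3f} bits, "
          f"mean = {np.mean(kld):8.3f} bits")
print("KLD < 0.05 bits means the axis marginal is flat to within estimator "
      "noise; > 0.5 bits marks an axis the walker failed to explore.")
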