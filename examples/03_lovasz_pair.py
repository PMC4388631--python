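"""A weak Loewner-John pair by the ellipsoid method.

On a 2-D rectangle the Lovász loop returns concentric ellipsoids
E_inner <= P <= E with E_inner a 1/D^{3/2} shrinkage of E.  The containments
are certified exactly: support-function evaluation per constraint for the
inner one, vertex membership for the outer one.
"""

import numpy as np

from fluxhr import diameter_spectrum, fva, lovasz_ellipsoid, make_hyperrectangle

rect = make_hyperrectangle(2, axis_lengths=[8.0, 0.5])
E, E_inner = lovasz_ellipsoid(rect)

print("outer diameters :", np.round(diameter_spectrum(E), 3))
print("inner diameters :", np.round(diameter_spectrum(E_inner), 3),
      f"(outer / D^1.5 = {2 ** 1.5:.3f})")

inner_ok = all(E_inner.support(g) <= h + 1e-9
               for g, h in zip(rect.G, rect.h))
res = fva(rect)
outer_ok = all(E.contains(v, tol=1e-9)
               for v in np.vstack([res.argmin, res.argmax]))
print(f"E_inner inside P: {inner_ok};  P inside E: {outer_ok}")
print("Directions drawn from E turn the elongated box into an (almost) "
      "round body for the hit-and-run walker.")
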