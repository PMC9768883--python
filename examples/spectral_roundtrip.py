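"""Spherical-harmonic transform of a field sampled at the 68 region centroids.

Shows the 68 -> 64 dimension reduction at truncation degree L = 7, the
exactness of the forward/inverse round trip, and which frequencies carry a
smooth field's energy.
"""

import numpy as np

from corticospec import SphericalPoint, build_basis, forward_sht, inverse_sht, make_atlas

atlas = make_atlas(seed=0)
points = [SphericalPoint(r.colatitude_rad, r.longitude_rad) for r in atlas.itertuples()]
basis = build_basis(points, L=7)
print(f"{len(points)} regions -> {basis.n_columns} real spectral terms at L=7")

# a smooth synthetic 'thickness' field: 2.7 mm plus a gentle gradient
field = 2.7 + 0.2 * np.cos([p.colatitude for p in points])
coeffs = forward_sht(field, basis)
back = inverse_sht(coeffs, basis)
print(f"round-trip max error: {np.abs(back - field).max():.2e}")

power = {l: float(np.sum(coeffs[basis.degrees == l] ** 2)) for l in range(8)}
print("per-degree power:", {l: round(p, 4) for l, p in power.items()})
print()
print("The mean sits on the (0,0) coefficient and the gradient on degree 1;")
print("higher degrees are numerically zero, which is what lets the model")
print("shrink high-frequency coefficient noise without touching the signal.")
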