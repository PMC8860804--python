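"""Directed phase lag index on a synthetic phase-lagged pair.

Generates two narrowband high-theta series where the second's phase
trails the first's by 0.3 rad on a controllable fraction of samples,
then recovers the directed phase lag index (dPLI) after band-pass
filtering and Hilbert phase extraction — the same path real data take.
"""

import numpy as np

from dirconn import analytic, dpli, gen_phase_lagged_pair

FS = 500.0
BAND = (7.0, 10.0)

print("coupling strength -> dPLI(x over y)   (0.5 = no consistent lead)")
for strength in (0.0, 0.4, 0.8, 1.0):
    x, y = gen_phase_lagged_pair(
        f_center=8.5, lag=0.3, strength=strength, n=20_000, fs=FS, seed=3
    )
    sx = analytic(x, FS, BAND)
    sy = analytic(y, FS, BAND)
    value = dpli(sx.phase, sy.phase)
    print(f"  strength {strength:.1f}  ->  dPLI {value:.3f}")

print(
    "\nWith full coupling every phase difference equals the planted +0.3 rad\n"
    "lag, so x leads y at every sample (dPLI = 1); with no coupling the\n"
    "lead direction is random and the dPLI sits near 0.5."
)
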