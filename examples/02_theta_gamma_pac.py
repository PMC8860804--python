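"""Theta-gamma phase-amplitude coupling and the normalized modulation index.

Generates a pair of series in which the gamma-band (30-80 Hz) amplitude
envelope of one follows the high-theta (7-10 Hz) phase of the other,
with a controllable modulation depth, and quantifies the coupling with
the normalized modulation index (nMI).  A circular-shift surrogate null
shows when the coupling is distinguishable from chance.
"""

import numpy as np

from dirconn import analytic, gen_pac_series, nmi

FS = 500.0
N = 15_000
rng = np.random.default_rng(5)

print("modulation depth -> nMI (and surrogate p at 200 shifts)")
for depth in (0.0, 0.3, 0.6, 1.0):
    theta, gamma = gen_pac_series(
        f_theta=8.5, f_gamma=50.0, depth=depth, pref_phase=0.0,
        n=N, fs=FS, seed=7, inter_regional=True,
    )
    phase = analytic(theta, FS, (7.0, 10.0), trim_samples=71).phase.ravel()
    amp = analytic(gamma, FS, (30.0, 80.0), trim_samples=71).amplitude.ravel()
    observed = nmi(phase, amp)
    null = [
        nmi(phase, np.roll(amp, int(rng.integers(len(amp) // 4, 3 * len(amp) // 4))))
        for _ in range(200)
    ]
    p = (1 + sum(v >= observed for v in null)) / 201
    print(f"  depth {depth:.1f}  ->  nMI {observed:.4f}   surrogate p = {p:.3f}")

print(
    "\nnMI grows monotonically with the planted modulation depth; at depth 0\n"
    "the envelope is constant and the index is indistinguishable from the\n"
    "time-shifted surrogate null."
)
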