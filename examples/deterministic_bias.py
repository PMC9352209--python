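"""How transconjugant self-transfer biases the end-point (SIM) estimate.

Integrates the deterministic mating model for two settings that differ
only in the transconjugant conjugation rate, then applies the end-point
estimator at increasing incubation times.  With identical rates the
estimate is flat and exact; with gamma_T >> gamma_D it inflates over
time, which is the failure mode the fluctuation (LDM) estimator avoids.
"""

import numpy as np

from ldmrate import (
    AssayObservation,
    InoculumState,
    RateParameters,
    ode_solve,
    sim_estimate,
)

init = InoculumState(D0=1e5, R0=1e5, T0=0.0)
equal = RateParameters(psi_D=1, psi_R=1, psi_T=1,
                       gamma_D=1e-14, gamma_T=1e-14)
unequal = equal.replace(gamma_T=1e-8)

grid = np.linspace(0, 8, 161)
print(f"{'t~ (hr)':>8} {'SIM, equal rates':>18} {'SIM, gamma_T=1e-8':>18}")
traj = {label: ode_solve(p, init, grid)
        for label, p in (("equal", equal), ("unequal", unequal))}
for tt in (1.0, 2.0, 4.0, 6.0, 8.0):
    row = []
    for label in ("equal", "unequal"):
        D, R, T = traj[label].at(tt)
        obs = AssayObservation(t_tilde=tt, N0=2e5, Dt=D, Rt=R, Tt=T,
                               Nt=D + R + T)
        row.append(sim_estimate(obs).value)
    print(f"{tt:8.1f} {row[0]:18.4g} {row[1]:18.4g}")

print(
    "\nThe generating donor conjugation rate is 1e-14 ml/(cell*hr) in both "
    "settings.\nWith equal rates the end-point estimate is exact and "
    "time-invariant; with a fast\ntransconjugant donor it overestimates by "
    "a growing factor."
)
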