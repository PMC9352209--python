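"""The first-transconjugant time t* and its analytic distribution.

Simulates mating assays with the exact Gillespie engine, records the time
of the first donor-to-recipient conjugation event in each culture, and
compares the empirical transconjugant-free fraction over time with the
analytic survival function p0(t).  Also prints the analytic mean of t*,
which is the recommended incubation time for the fluctuation assay.
"""

import numpy as np

from ldmrate import (
    InoculumState,
    RateParameters,
    SimulationConfig,
    mean_tstar_analytic,
    p0_analytic,
    run_ensemble,
)

params = RateParameters(psi_D=1, psi_R=1, psi_T=1,
                        gamma_D=1e-6, gamma_T=1e-6)
init = InoculumState(D0=100, R0=100)

cfg = SimulationConfig(params=params, init=init, t_max=5.0,
                       engine="gillespie")
ens = run_ensemble(cfg, 2000, master_seed=12)

print(f"{'t (hr)':>7} {'simulated p0':>13} {'analytic p0':>12}")
for t in (1.0, 1.5, 2.0, 2.5, 3.0, 3.5):
    print(f"{t:7.1f} {ens.fraction_t_free(t):13.3f} "
          f"{p0_analytic(params, init, t):12.3f}")

t_bar = mean_tstar_analytic(params, init)
ts = ens.t_stars
print(f"\nanalytic  E[t*] = {t_bar:.3f} hr")
print(f"simulated E[t*] = {np.nanmean(ts):.3f} hr "
      f"({np.isnan(ts).sum()} of {ts.size} runs event-free by t_max)")
print("\nThe transconjugant-free fraction tracks the analytic survival "
      "curve; reading\nthe assay near E[t*] keeps p0 away from 0 and 1, "
      "where the fluctuation\nestimate is most informative.")
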