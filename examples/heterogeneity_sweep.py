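"""Robustness to transconjugant-rate heterogeneity: LDM vs SIM medians.

Sweeps the transconjugant conjugation rate gamma_T over several decades
while the donor rate stays at 1e-6, choosing each cell's incubation times
by the study rules (average t* for the fluctuation readout, mean T = 50
for the end-point readout).  The fluctuation estimate keys on the first
donor-to-recipient event only, so it is insensitive to gamma_T; the
end-point estimate drifts upward as transconjugants amplify themselves,
and at the most extreme setting most runs have no transconjugants at all
at the (very early) readout, pushing the SIM median to zero.
"""

from ldmrate import (
    BatchDesign,
    InoculumState,
    RateParameters,
    SimulationConfig,
    parameter_sweep,
)

params = RateParameters(psi_D=1, psi_R=1, psi_T=1,
                        gamma_D=1e-6, gamma_T=1e-6)
init = InoculumState(D0=100, R0=100)
cfg = SimulationConfig(params=params, init=init, t_max=6.0, engine="hybrid")
design = BatchDesign(n_populations=500, populations_per_ldm=100,
                     master_seed=21)

values = [1e-8, 1e-6, 1e-4, 1e-2]
sweep = parameter_sweep(cfg, "conjugation", values, design)

print(f"{'gamma_T':>9} {'t~_LDM':>7} {'t~_SIM':>7} "
      f"{'LDM median':>12} {'SIM median':>12} {'SIM zeros':>9}")
for cell in sweep.cells:
    print(f"{cell.axis_value:9.0e} {cell.t_ldm:7.2f} {cell.t_sim:7.2f} "
          f"{cell.ldm_summary.median:12.3g} {cell.sim_summary.median:12.3g} "
          f"{cell.sim_summary.n_zero:9d}")

print("\nTrue donor rate: 1e-06.  The LDM median stays pinned to it "
      "across 6 decades\nof gamma_T; the SIM median drifts upward with "
      "gamma_T and collapses to zero\nat gamma_T = 1e-2, where the "
      "mean-T=50 readout comes before most runs have\nany transconjugant.")
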