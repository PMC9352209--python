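"""Simulation-study machinery: batching, incubation-time selection, sweeps.

The study design mirrors a fluctuation experiment run in silico: an
ensemble of independent stochastic mating assays is split into disjoint
blocks (default 100 populations per block).  Each block yields one
fluctuation (LDM) estimate — the block's transconjugant-free fraction
supplies ``p0_hat`` and one seeded-random population in the block supplies
the density measurements — and the same designated population yields one
end-point (SIM) estimate.  With the default 10,000 populations this gives
100 estimates of each kind per parameter setting.

Incubation times are chosen per parameter setting: the fluctuation assay
reads out at the average first-event time t*, the end-point assay at the
time the mean transconjugant count reaches 50.  Sweeps over incubation
time or over model parameters collect the resulting estimate
distributions, apply the 90% finite-nonzero inclusion rule per method, and
summarize each distribution with quartiles and 1.5*IQR whiskers clipped to
the data range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import ode_solve
from .errors import DomainError, LdmError
from .estimators import (
    AssayObservation,
    EstimateResult,
    ldm_endpoint,
    sim_estimate,
)
from .simulate import Ensemble, SimulationConfig, run_ensemble

__all__ = [
    "BatchDesign",
    "DistributionSummary",
    "SweepResult",
    "ldm_batch_estimates",
    "sim_batch_estimates",
    "choose_t_ldm",
    "choose_t_sim",
    "incubation_sweep",
    "parameter_sweep",
    "summarize_distribution",
    "compare_estimates",
    "geometric_mean",
]


@dataclass(frozen=True)
class BatchDesign:
    """How an ensemble is partitioned into estimates.

    ``n_populations`` must be divisible by ``populations_per_ldm``.  The
    density-measurement population of each block is drawn from a
    per-block substream of ``master_seed`` so sweeps are replayable.
    """

    n_populations: int = 10_000
    populations_per_ldm: int = 100
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations % self.populations_per_ldm != 0:
            raise DomainError(
                f"n_populations ({self.n_populations}) must be divisible by "
                f"populations_per_ldm ({self.populations_per_ldm})"
            )

    @property
    def n_estimates(self) -> int:
        return self.n_populations // self.populations_per_ldm

    def density_run_indices(self, n_blocks: int) -> list[int]:
        """Within-block index of the density population, per block."""
        out = []
        for k in range(n_blocks):
            rng = np.random.default_rng([self.master_seed, k])
            out.append(int(rng.integers(self.populations_per_ldm)))
        return out


def _blocks(ensemble: Ensemble, design: BatchDesign):
    m = design.populations_per_ldm
    if len(ensemble) < m:
        raise DomainError(
            f"ensemble has {len(ensemble)} runs, fewer than "
            f"populations_per_ldm = {m}"
        )
    n_blocks = len(ensemble) // m
    picks = design.density_run_indices(n_blocks)
    for k in range(n_blocks):
        block = ensemble.runs[k * m:(k + 1) * m]
        yield k, block, block[picks[k]]


def ldm_batch_estimates(
    ensemble: Ensemble,
    t_tilde: float,
    design: BatchDesign,
) -> list[EstimateResult]:
    """One fluctuation estimate per disjoint block of the ensemble.

    Per block: ``p0_hat`` is the fraction of runs with no transconjugant by
    ``t_tilde``; the designated density run supplies D and R counts at
    t = 0 and t = t_tilde; the end-point estimator is applied with
    f = 1/volume.  Blocks where every run has transconjugants produce
    flagged invalid estimates rather than being dropped.
    """
    vol = ensemble.config.volume
    results = []
    for _k, block, density_run in _blocks(ensemble, design):
        free = sum(1 for r in block
                   if r.t_star is None or r.t_star > t_tilde)
        p0_hat = free / len(block)
        D0, R0, _ = density_run.densities_at(0.0)
        Dt, Rt, _ = density_run.densities_at(t_tilde)
        obs = AssayObservation(
            t_tilde=t_tilde, D0=D0, R0=R0, Dt=Dt, Rt=Rt,
            f=1.0 / vol, p0_hat=p0_hat, n_wells=len(block),
        )
        results.append(ldm_endpoint(obs))
    return results


def sim_batch_estimates(
    ensemble: Ensemble,
    t_tilde: float,
    design: BatchDesign,
) -> list[EstimateResult]:
    """One end-point estimate per block, from the block's density run."""
    vol = ensemble.config.volume
    results = []
    for _k, _block, run in _blocks(ensemble, design):
        D0, R0, T0 = run.densities_at(0.0)
        Dt, Rt, Tt = run.densities_at(t_tilde)
        obs = AssayObservation(
            t_tilde=t_tilde, D0=D0, R0=R0, N0=D0 + R0 + T0,
            Dt=Dt, Rt=Rt, Tt=Tt, Nt=Dt + Rt + Tt, f=1.0 / vol,
        )
        results.append(sim_estimate(obs))
    return results


def choose_t_ldm(ensemble: Ensemble) -> float:
    """Incubation time for the fluctuation readout: the average t*.

    Runs that never produced a transconjugant are excluded from the mean;
    their count is available as ``np.isnan(ensemble.t_stars).sum()``.
    """
    ts = ensemble.t_stars
    ts = ts[~np.isnan(ts)]
    if ts.size == 0:
        raise LdmError(
            "no run produced a transconjugant; cannot choose an incubation "
            "time from t*"
        )
    return float(ts.mean())


def choose_t_sim(ensemble: Ensemble, threshold: float = 50.0) -> float:
    """Incubation time for the end-point readout.

    The earliest time at which the mean transconjugant count reaches
    ``threshold``, linearly interpolated between sample times.
    """
    mean_T = np.mean([r.T for r in ensemble.runs], axis=0)
    times = ensemble.runs[0].sample_times
    idx = np.nonzero(mean_T >= threshold)[0]
    if idx.size == 0:
        raise LdmError(
            f"mean transconjugant count never reached {threshold} within "
            f"t_max = {ensemble.config.t_max} hr; rerun with a longer t_max"
        )
    i = int(idx[0])
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    y0, y1 = mean_T[i - 1], mean_T[i]
    return float(t0 + (threshold - y0) / (y1 - y0) * (t1 - t0))


@dataclass
class DistributionSummary:
    """Boxplot-style summary of an estimate distribution.

    Quantiles use linear interpolation (numpy default, type 7); whiskers
    extend to 1.5*IQR beyond the quartiles but are clipped to the data
    range.  Zero estimates are retained in the statistics; invalid ones are
    excluded but counted.
    """

    n: int
    n_invalid: int
    n_zero: int
    n_finite_nonzero: int
    mean: float
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float

    @property
    def fraction_finite_nonzero(self) -> float:
        return self.n_finite_nonzero / self.n if self.n else 0.0

    def to_dict(self) -> dict:
        return dict(self.__dict__,
                    fraction_finite_nonzero=self.fraction_finite_nonzero)


def summarize_distribution(estimates: list[EstimateResult]
                           ) -> DistributionSummary:
    if not estimates:
        raise DomainError("need at least one estimate to summarize")
    values = np.array([e.value for e in estimates if e.valid])
    n_invalid = sum(1 for e in estimates if not e.valid)
    n_zero = int(np.sum(values == 0))
    n_fnz = sum(1 for e in estimates if e.is_finite_nonzero)
    if values.size == 0:
        nan = math.nan
        return DistributionSummary(len(estimates), n_invalid, 0, 0,
                                   nan, nan, nan, nan, nan, nan)
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo = max(values.min(), q1 - 1.5 * iqr)
    hi = min(values.max(), q3 + 1.5 * iqr)
    return DistributionSummary(
        n=len(estimates), n_invalid=n_invalid, n_zero=n_zero,
        n_finite_nonzero=n_fnz, mean=float(values.mean()),
        median=float(med), q1=float(q1), q3=float(q3),
        whisker_lo=float(lo), whisker_hi=float(hi),
    )


def geometric_mean(estimates: list[EstimateResult]) -> float:
    """Geometric mean of the finite nonzero valid estimates."""
    vals = [e.value for e in estimates if e.is_finite_nonzero]
    if not vals:
        raise DomainError("no finite nonzero estimates")
    return float(stats.gmean(vals))


@dataclass
class ComparisonResult:
    t_statistic: float
    df: float
    p_value: float
    n_a: int
    n_b: int
    n_excluded_a: int
    n_excluded_b: int


def compare_estimates(group_a: list[EstimateResult],
                      group_b: list[EstimateResult]) -> ComparisonResult:
    """Welch's two-sided t test on log10 estimates.

    Zero and invalid estimates cannot be log-transformed; they are excluded
    and their counts reported.
    """
    a = np.log10([e.value for e in group_a if e.is_finite_nonzero])
    b = np.log10([e.value for e in group_b if e.is_finite_nonzero])
    if a.size < 2 or b.size < 2:
        raise DomainError(
            "need at least 2 valid nonzero estimates per group for a t test"
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        df = float(a.size + b.size - 2)
    else:
        num = (va / a.size + vb / b.size) ** 2
        den = (va / a.size) ** 2 / (a.size - 1) \
            + (vb / b.size) ** 2 / (b.size - 1)
        df = float(num / den)
    return ComparisonResult(
        t_statistic=float(res.statistic), df=df,
        p_value=float(res.pvalue), n_a=a.size, n_b=b.size,
        n_excluded_a=len(group_a) - a.size,
        n_excluded_b=len(group_b) - b.size,
    )


@dataclass
class SweepCell:
    """Estimates for one axis value (or one incubation time)."""

    axis_value: float
    t_ldm: float | None
    t_sim: float | None
    ldm: list[EstimateResult] = field(default_factory=list)
    sim: list[EstimateResult] = field(default_factory=list)
    ldm_summary: DistributionSummary | None = None
    sim_summary: DistributionSummary | None = None
    ldm_included: bool = True
    sim_included: bool = True


@dataclass
class SweepResult:
    """Tidy container for a sweep: one :class:`SweepCell` per axis value."""

    axis_name: str
    cells: list[SweepCell]
    design: BatchDesign

    @property
    def values(self) -> list[float]:
        return [c.axis_value for c in self.cells]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for cell in self.cells:
            for method, ests, inc in (("LDM", cell.ldm, cell.ldm_included),
                                      ("SIM", cell.sim, cell.sim_included)):
                for i, e in enumerate(ests):
                    rows.append({
                        self.axis_name: cell.axis_value,
                        "method": method, "estimate_index": i,
                        "value": e.value, "valid": e.valid,
                        "reason": e.reason, "included": inc,
                        "t_tilde": cell.t_ldm if method == "LDM"
                        else cell.t_sim,
                    })
        return pd.DataFrame(rows)


# the per-interval / per-cell inclusion rule: >= 90% of estimates must be
# finite and nonzero, applied separately per method
_INCLUSION_FRACTION = 0.90


def _included(estimates: list[EstimateResult]) -> bool:
    fnz = sum(1 for e in estimates if e.is_finite_nonzero)
    return fnz >= _INCLUSION_FRACTION * len(estimates)


def incubation_sweep(
    config: SimulationConfig,
    design: BatchDesign,
    t_grid=None,
    step: float = 0.5,
    max_total: float = 1e9,
) -> SweepResult:
    """Estimate distributions on a grid of incubation times.

    The default grid runs in 30-minute steps from ``step`` until the
    deterministic total density reaches ``max_total`` cfu/ml (or
    ``config.t_max``, whichever is earlier).  Intervals where fewer than
    90% of a method's estimates are finite and nonzero are flagged
    excluded, separately for each method since their valid windows differ.
    """
    if t_grid is None:
        fine = np.linspace(0.0, config.t_max, 512)
        traj = ode_solve(config.params, config.init, fine)
        below = fine[traj.N < max_total]
        t_end = float(below[-1]) if below.size else config.t_max
        t_grid = np.arange(step, t_end + 1e-9, step)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise DomainError("incubation-time grid is empty")

    sample = np.concatenate([[0.0], t_grid])
    ens = run_ensemble(
        config.replace(sample_times=tuple(sample),
                       t_max=max(config.t_max, float(t_grid[-1]))),
        design.n_populations, design.master_seed,
    )
    cells = []
    for tt in t_grid:
        ldm = ldm_batch_estimates(ens, float(tt), design)
        sim = sim_batch_estimates(ens, float(tt), design)
        cells.append(SweepCell(
            axis_value=float(tt), t_ldm=float(tt), t_sim=float(tt),
            ldm=ldm, sim=sim,
            ldm_summary=summarize_distribution(ldm),
            sim_summary=summarize_distribution(sim),
            ldm_included=_included(ldm), sim_included=_included(sim),
        ))
    return SweepResult(axis_name="t_tilde", cells=cells, design=design)


def _estimates_at_chosen_times(
    config: SimulationConfig,
    design: BatchDesign,
    sim_threshold: float,
    scan_step: float = 0.1,
    max_extensions: int = 3,
) -> SweepCell:
    """Run one parameter setting end to end.

    Pass 1 samples a fine grid to locate the method-specific incubation
    times (average t* for the fluctuation readout, mean-T = threshold for
    the end-point readout); pass 2 replays the identical runs sampled at
    exactly those times.  If the threshold is not reached, the horizon is
    doubled a few times before giving up.
    """
    cfg = config
    for attempt in range(max_extensions + 1):
        grid = np.arange(0.0, cfg.t_max + 1e-9, scan_step)
        ens = run_ensemble(cfg.replace(sample_times=tuple(grid)),
                           design.n_populations, design.master_seed)
        t_ldm = choose_t_ldm(ens)
        try:
            t_sim = choose_t_sim(ens, threshold=sim_threshold)
            break
        except LdmError:
            if attempt == max_extensions:
                raise
            cfg = cfg.replace(t_max=cfg.t_max * 2)
    # replay the identical runs, sampled exactly at the chosen times; the
    # horizon is trimmed to the latest readout (sampling consumes no
    # randomness, so trajectories up to it are unchanged)
    times = sorted({0.0, t_ldm, t_sim})
    ens2 = run_ensemble(
        cfg.replace(sample_times=tuple(times), t_max=max(times)),
        design.n_populations, design.master_seed,
    )
    ldm = ldm_batch_estimates(ens2, t_ldm, design)
    sim = sim_batch_estimates(ens2, t_sim, design)
    return SweepCell(
        axis_value=math.nan, t_ldm=t_ldm, t_sim=t_sim, ldm=ldm, sim=sim,
        ldm_summary=summarize_distribution(ldm),
        sim_summary=summarize_distribution(sim),
        ldm_included=_included(ldm), sim_included=_included(sim),
    )


def parameter_sweep(
    base_config: SimulationConfig,
    axis: str,
    values,
    design: BatchDesign,
    sim_threshold: float = 50.0,
) -> SweepResult:
    """Sweep growth-rate or conjugation-rate heterogeneity.

    ``axis='growth'`` sets psi_D = psi_T to each value (plasmid cost or
    benefit relative to the recipient); ``axis='conjugation'`` sets gamma_T
    to each value.  Each cell chooses its own incubation times.
    """
    if axis not in ("growth", "conjugation"):
        raise DomainError(f"axis must be 'growth' or 'conjugation', "
                          f"got {axis!r}")
    cells = []
    for v in values:
        if v <= 0:
            raise DomainError(f"axis values must be positive, got {v}")
        p = base_config.params
        if axis == "growth":
            p = p.replace(psi_D=float(v), psi_T=float(v))
        else:
            p = p.replace(gamma_T=float(v))
        cell = _estimates_at_chosen_times(
            base_config.replace(params=p), design, sim_threshold)
        cell.axis_value = float(v)
        cells.append(cell)
    name = "psi_D_psi_T" if axis == "growth" else "gamma_T"
    return SweepResult(axis_name=name, cells=cells, design=design)
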