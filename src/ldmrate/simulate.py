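"""Stochastic realizations of the mating assay.

Two engines produce :class:`StochasticRun` objects:

``gillespie_run``
    Exact stochastic simulation (direct-method SSA) over the five reactions

        D -> 2D            rate psi_D * D
        R -> 2R            rate psi_R * R
        T -> 2T            rate psi_T * T
        D + R -> D + T     rate gamma_D * D * R / V
        T + R -> 2T        rate gamma_T * T * R / V

    with integer counts in a culture of volume ``V`` ml.  The time of the
    first D+R -> D+T firing is recorded as ``t_star``.

``hybrid_run``
    A fast engine consistent with the first-event theory: donors and
    recipients follow their deterministic exponentials while the
    transconjugant count is an exact inhomogeneous birth process
    (immigration ``gamma_D*D(t)*R(t)/V`` plus per-capita
    ``psi_T + gamma_T*R(t)/V``) simulated by thinning.  ``t_star`` is then
    distributed exactly with survival function
    :func:`ldmrate.core_model.p0_analytic`.

Both engines consume only uniform variates from a ``numpy.random.Generator``
so that runs are bitwise reproducible from their recorded seed.  The SSA
inner loop is JIT-compiled with numba when available; the pure-Python
fallback draws the identical random stream.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import InoculumState, RateParameters
from .errors import DomainError, NoEventError, SimulationError

__all__ = [
    "SimulationConfig",
    "StochasticRun",
    "Ensemble",
    "gillespie_run",
    "hybrid_run",
    "hybrid_tstar_sample",
    "run_ensemble",
    "resample_ensemble",
]

# refuse exact-SSA configs whose expected event count exceeds this
_MAX_EXPECTED_EVENTS = 1e8
# status codes returned by the SSA core
_OK, _OVERFLOW = 0, 2


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce a stochastic mating-assay run.

    ``sample_times`` is the grid (hr) at which counts are recorded; it
    defaults to ``[0, t_max]``.  ``population_cap`` stops a run once the
    total count reaches it (default 1e9).  ``t_cap`` saturates the hybrid
    transconjugant count to keep runaway ``gamma_T`` regimes affordable;
    saturated runs are flagged.
    """

    params: RateParameters
    init: InoculumState
    t_max: float
    volume: float = 1.0
    population_cap: float = 1e9
    seed: int = 0
    engine: str = "gillespie"
    sample_times: tuple[float, ...] | None = None
    t_cap: int = 100_000

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise DomainError(f"volume must be > 0, got {self.volume}")
        if self.t_max <= 0:
            raise DomainError(f"t_max must be > 0, got {self.t_max}")
        if self.engine not in ("gillespie", "hybrid"):
            raise DomainError(f"unknown engine {self.engine!r}")
        if self.sample_times is not None:
            st = tuple(float(t) for t in self.sample_times)
            if any(b <= a for a, b in zip(st, st[1:])):
                raise DomainError("sample_times must be strictly increasing")
            object.__setattr__(self, "sample_times", st)

    @property
    def grid(self) -> np.ndarray:
        if self.sample_times is None:
            return np.array([0.0, self.t_max])
        return np.asarray(self.sample_times, dtype=float)

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def initial_counts(self) -> tuple[int, int, int]:
        out = []
        for name, dens in (("D0", self.init.D0), ("R0", self.init.R0),
                           ("T0", self.init.T0)):
            x = dens * self.volume
            n = round(x)
            if dens > 0 and n == 0:
                raise DomainError(
                    f"{name} = {dens} cfu/ml in {self.volume} ml rounds to "
                    "zero cells; increase the volume or the density"
                )
            if x < 100 and abs(x - n) > 1e-6:
                raise DomainError(
                    f"{name} * volume = {x} is not a whole number of cells"
                )
            out.append(int(n))
        return tuple(out)


@dataclass
class StochasticRun:
    """One stochastic realization: counts on a sample grid plus ``t_star``."""

    sample_times: np.ndarray
    D: np.ndarray
    R: np.ndarray
    T: np.ndarray
    t_star: float | None
    t_end: float
    final: tuple[int, int, int]
    seed: int
    volume: float
    engine: str
    saturated: bool = False

    def counts_at(self, t: float) -> tuple[int, int, int]:
        """Integer counts at sample time ``t`` (must be on the grid)."""
        i = int(np.argmin(np.abs(self.sample_times - t)))
        if abs(self.sample_times[i] - t) > 1e-9 * max(1.0, abs(t)):
            raise KeyError(
                f"time {t} is not on the run's sample grid; resample the "
                "ensemble with this time included"
            )
        return int(self.D[i]), int(self.R[i]), int(self.T[i])

    def densities_at(self, t: float) -> tuple[float, float, float]:
        d, r, tt = self.counts_at(t)
        return d / self.volume, r / self.volume, tt / self.volume

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"time": self.sample_times, "D": self.D, "R": self.R,
             "T": self.T}
        )
        df["seed"] = self.seed
        return df


# ---------------------------------------------------------------------------
# exact SSA core


def _ssa_core_py(gen, D, R, T, psiD, psiR, psiT, gD, gT, invV,
                 t_max, cap, sample_times, outD, outR, outT):
    t = 0.0
    t_star = -1.0
    si = 0
    ns = sample_times.shape[0]
    while True:
        a1 = psiD * D
        a2 = psiR * R
        a3 = psiT * T
        a4 = gD * D * R * invV
        a5 = gT * T * R * invV
        a0 = a1 + a2 + a3 + a4 + a5
        if not (a0 < 1e300):
            return t_star, t, D, R, T, _OVERFLOW
        if a0 <= 0.0:
            break
        t_new = t - math.log(gen.random()) / a0
        while si < ns and sample_times[si] < t_new:
            outD[si] = D
            outR[si] = R
            outT[si] = T
            si += 1
        if t_new > t_max:
            t = t_max
            break
        t = t_new
        u = gen.random() * a0
        if u < a1:
            D += 1.0
        elif u < a1 + a2:
            R += 1.0
        elif u < a1 + a2 + a3:
            T += 1.0
        elif u < a1 + a2 + a3 + a4:
            R -= 1.0
            T += 1.0
            if t_star < 0.0:
                t_star = t
        else:
            R -= 1.0
            T += 1.0
        if D + R + T >= cap:
            break
    while si < ns:
        outD[si] = D
        outR[si] = R
        outT[si] = T
        si += 1
    return t_star, t, D, R, T, _OK


_ssa_core = None  # resolved lazily: numba-compiled if possible


def _resolve_ssa_core():
    global _ssa_core
    if _ssa_core is not None:
        return _ssa_core
    try:
        from numba import njit

        _ssa_core = njit(cache=False)(_ssa_core_py)
    except Exception:  # pragma: no cover - numba always present in CI image
        _ssa_core = _ssa_core_py
    return _ssa_core


def gillespie_run(config: SimulationConfig, seed: int | None = None
                  ) -> StochasticRun:
    """Run the exact SSA for one culture.

    Raises :class:`SimulationError` if the expected number of division
    events exceeds 1e8 (use the hybrid engine for such configurations) or
    if a propensity overflows.
    """
    p, init = config.params, config.init
    D0, R0, T0 = config.initial_counts()
    run_seed = config.seed if seed is None else seed

    # projected division-event count, bounded by the population cap
    proj = 0.0
    for n0, psi in ((D0, p.psi_D), (R0, p.psi_R), (T0, p.psi_T)):
        arg = psi * config.t_max
        grown = math.inf if arg > 700 else n0 * math.exp(arg)
        proj += min(grown, config.population_cap) - n0
    if proj > _MAX_EXPECTED_EVENTS:
        raise SimulationError(
            f"expected ~{proj:.2g} events for this configuration; the exact "
            "SSA refuses > 1e8 — use engine='hybrid'"
        )

    grid = config.grid
    outD = np.zeros(grid.size, dtype=np.int64)
    outR = np.zeros(grid.size, dtype=np.int64)
    outT = np.zeros(grid.size, dtype=np.int64)
    gen = np.random.default_rng(run_seed)
    core = _resolve_ssa_core()
    args = (gen, float(D0), float(R0), float(T0),
            p.psi_D, p.psi_R, p.psi_T, p.gamma_D, p.gamma_T,
            1.0 / config.volume, float(config.t_max),
            float(config.population_cap), grid, outD, outR, outT)
    try:
        t_star, t_end, Df, Rf, Tf, status = core(*args)
    except Exception:
        # numba typing failure: fall back permanently to pure Python
        global _ssa_core
        _ssa_core = _ssa_core_py
        gen = np.random.default_rng(run_seed)
        args = (gen,) + args[1:]
        t_star, t_end, Df, Rf, Tf, status = _ssa_core_py(*args)
    if status == _OVERFLOW:
        raise SimulationError(
            f"propensity overflow at counts D={Df:.3g}, R={Rf:.3g}, "
            f"T={Tf:.3g} (t = {t_end:.4g} hr)"
        )
    return StochasticRun(
        sample_times=grid, D=outD, R=outR, T=outT,
        t_star=None if t_star < 0 else float(t_star),
        t_end=float(t_end), final=(int(Df), int(Rf), int(Tf)),
        seed=int(run_seed), volume=config.volume, engine="gillespie",
    )


# ---------------------------------------------------------------------------
# hybrid engine


def hybrid_tstar_sample(
    params: RateParameters,
    init: InoculumState,
    volume: float = 1.0,
    u: float | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Draw the first-event time t* by inverting its survival function.

    With s = psi_D + psi_R and whole-culture initial hazard
    ``h0 = gamma_D * D0 * R0 * volume``,

        t* = (1/s) * ln(1 + s * (-ln u) / h0)      (s > 0)
        t* = (-ln u) / h0                          (s = 0)

    where ``u`` is Uniform(0, 1); the samples have survival function
    ``p0_analytic``.
    """
    if init.T0 != 0:
        raise DomainError("t* sampling assumes T0 = 0")
    h0 = params.gamma_D * init.D0 * init.R0 * volume
    if h0 <= 0:
        raise NoEventError("gamma_D * D0 * R0 = 0: no first event exists")
    if u is None:
        u = (rng or np.random.default_rng()).random()
    if not 0.0 < u < 1.0:
        raise DomainError(f"u must be in (0, 1), got {u}")
    s = params.psi_sum
    neg_log_u = -math.log(u)
    if s > 0:
        return math.log1p(s * neg_log_u / h0) / s
    return neg_log_u / h0


def _hybrid_core_py(gen, D0c, R0c, T0c, psiD, psiR, psiT, gD, gT, invV,
                    t_max, cap, t_cap, sample_times, outD, outR, outT,
                    window):
    """Thinning simulation of the transconjugant birth process.

    The majorant is piecewise constant, refreshed at every event and at
    least every ``window`` hours; the birth rate is nondecreasing in time
    for fixed T (all rates nonnegative), so evaluating it at the window
    end bounds it on the window.
    """
    t = 0.0
    T = float(T0c)
    t_star = -1.0
    si = 0
    ns = sample_times.shape[0]
    saturated = False

    while t < t_max:
        w1 = t + window
        if w1 > t_max:
            w1 = t_max
        Dw = D0c * math.exp(psiD * w1)
        Rw = R0c * math.exp(psiR * w1)
        if Dw + Rw + T >= cap:
            break
        lam_max = gD * Dw * Rw * invV + gT * T * Rw * invV + psiT * T
        if lam_max <= 0.0:
            te = w1
            event = False
        else:
            dt = -math.log(gen.random()) / lam_max
            if t + dt >= w1:
                te = w1
                event = False
            else:
                te = t + dt
                event = True
        limit = te - 1e-12 if event else te
        while si < ns and sample_times[si] <= limit + 1e-15:
            sv = sample_times[si]
            outD[si] = int(D0c * math.exp(psiD * sv) + 0.5)
            outR[si] = int(R0c * math.exp(psiR * sv) + 0.5)
            outT[si] = int(T)
            si += 1
        if event:
            Dt = D0c * math.exp(psiD * te)
            Rt = R0c * math.exp(psiR * te)
            a_d = gD * Dt * Rt * invV
            a_t = gT * T * Rt * invV
            a_s = psiT * T
            v = gen.random() * lam_max
            if v < a_d:
                T += 1.0
                if t_star < 0.0:
                    t_star = te
            elif v < a_d + a_t + a_s:
                T += 1.0
            # else: thinned, no event
        t = te
        if T >= t_cap:
            saturated = True
            break

    # remaining samples: D, R keep their closed forms up to the stop time
    t_end = t
    while si < ns:
        sv = sample_times[si]
        if sv > t_end:
            sv = t_end
        outD[si] = int(D0c * math.exp(psiD * sv) + 0.5)
        outR[si] = int(R0c * math.exp(psiR * sv) + 0.5)
        outT[si] = int(T)
        si += 1
    return t_star, t_end, T, saturated


_hybrid_core = None  # resolved lazily, like the SSA core


def _resolve_hybrid_core():
    global _hybrid_core
    if _hybrid_core is not None:
        return _hybrid_core
    try:
        from numba import njit

        _hybrid_core = njit(cache=False)(_hybrid_core_py)
    except Exception:  # pragma: no cover
        _hybrid_core = _hybrid_core_py
    return _hybrid_core


def hybrid_run(config: SimulationConfig, seed: int | None = None
               ) -> StochasticRun:
    """Run the hybrid engine: deterministic D and R, stochastic T."""
    p = config.params
    D0, R0, T0 = config.initial_counts()
    run_seed = config.seed if seed is None else seed
    grid = config.grid
    outD = np.zeros(grid.size, dtype=np.int64)
    outR = np.zeros(grid.size, dtype=np.int64)
    outT = np.zeros(grid.size, dtype=np.int64)
    gen = np.random.default_rng(run_seed)
    core = _resolve_hybrid_core()
    args = (gen, float(D0), float(R0), float(T0),
            p.psi_D, p.psi_R, p.psi_T, p.gamma_D, p.gamma_T,
            1.0 / config.volume, float(config.t_max),
            float(config.population_cap), float(config.t_cap),
            grid, outD, outR, outT, 0.1)
    try:
        t_star, t_end, Tf, saturated = core(*args)
    except Exception:
        global _hybrid_core
        _hybrid_core = _hybrid_core_py
        gen = np.random.default_rng(run_seed)
        args = (gen,) + args[1:]
        t_star, t_end, Tf, saturated = _hybrid_core_py(*args)
    Df = int(round(D0 * math.exp(p.psi_D * t_end)))
    Rf = int(round(R0 * math.exp(p.psi_R * t_end)))
    return StochasticRun(
        sample_times=grid, D=outD, R=outR, T=outT,
        t_star=None if t_star < 0 else float(t_star),
        t_end=float(t_end), final=(Df, Rf, int(Tf)),
        seed=int(run_seed), volume=config.volume, engine="hybrid",
        saturated=saturated,
    )


# ---------------------------------------------------------------------------
# ensembles


@dataclass
class Ensemble:
    """A set of independent runs sharing one configuration.

    Per-run seeds are derived from ``master_seed`` through a
    ``numpy.random.SeedSequence`` so the whole ensemble is bitwise
    reproducible from ``(config, master_seed)``.
    """

    config: SimulationConfig
    master_seed: int
    runs: list[StochasticRun] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.runs)

    @property
    def sample_times(self) -> np.ndarray:
        if self.runs:
            return self.runs[0].sample_times
        return self.config.grid

    @property
    def t_stars(self) -> np.ndarray:
        """t* per run; NaN where no first event occurred."""
        return np.array(
            [math.nan if r.t_star is None else r.t_star for r in self.runs]
        )

    def fraction_t_free(self, t: float) -> float:
        """Fraction of runs still transconjugant-free at time ``t``."""
        ts = self.t_stars
        return float(np.mean(np.isnan(ts) | (ts > t)))

    def mean_counts(self) -> pd.DataFrame:
        """Mean D, R, T counts over runs at each sample time."""
        D = np.mean([r.D for r in self.runs], axis=0)
        R = np.mean([r.R for r in self.runs], axis=0)
        T = np.mean([r.T for r in self.runs], axis=0)
        return pd.DataFrame(
            {"time": self.sample_times, "D": D, "R": R, "T": T}
        )

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for i, r in enumerate(self.runs):
            df = r.to_dataframe()
            df.insert(0, "run", i)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def summary_dict(self) -> dict:
        return {
            "engine": self.config.engine,
            "master_seed": self.master_seed,
            "n_runs": len(self.runs),
            "seeds": [r.seed for r in self.runs],
            "t_star": [r.t_star for r in self.runs],
            "n_saturated": sum(r.saturated for r in self.runs),
            "config": {
                "params": self.config.params.to_dict(),
                "init": self.config.init.to_dict(),
                "volume": self.config.volume,
                "t_max": self.config.t_max,
                "population_cap": self.config.population_cap,
                "t_cap": self.config.t_cap,
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=1)


def _derive_seeds(master_seed: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence(master_seed)
    return ss.generate_state(n, dtype=np.uint32)


def run_ensemble(config: SimulationConfig, n: int, master_seed: int
                 ) -> Ensemble:
    """Run ``n`` independent realizations with derived per-run seeds."""
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    runner = gillespie_run if config.engine == "gillespie" else hybrid_run
    seeds = _derive_seeds(master_seed, n)
    runs = [runner(config, seed=int(s)) for s in seeds]
    return Ensemble(config=config, master_seed=master_seed, runs=runs)


def resample_ensemble(ensemble: Ensemble, sample_times) -> Ensemble:
    """Re-run an ensemble with a new sample grid.

    Sampling consumes no randomness, so the re-run trajectories are
    identical to the originals; only the recorded grid changes.
    """
    cfg = ensemble.config.replace(sample_times=tuple(sample_times))
    return run_ensemble(cfg, len(ensemble), ensemble.master_seed)
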