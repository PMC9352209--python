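"""Deterministic mating-assay model and analytic first-event theory.

The mating assay mixes plasmid-bearing donors (density ``D``, cfu/ml) with
plasmid-free recipients (``R``); recipients that acquire the plasmid become
transconjugants (``T``).  With per-capita growth rates ``psi_D``, ``psi_R``,
``psi_T`` (hr^-1) and mass-action conjugation rates ``gamma_D`` (donor to
recipient) and ``gamma_T`` (transconjugant to recipient, ml cell^-1 hr^-1),
the densities obey

    dD/dt = psi_D * D
    dR/dt = psi_R * R - gamma_D*D*R - gamma_T*T*R
    dT/dt = psi_T * T + gamma_D*D*R + gamma_T*T*R

Because the assay starts with no transconjugants, the first transconjugant
can only arise from a donor-recipient conjugation.  Treating donors and
recipients as deterministic exponential populations, the number of
donor-to-recipient conjugation events by time t is an inhomogeneous Poisson
count with cumulative hazard

    Lambda(t) = gamma_D * D0 * R0 / (psi_D + psi_R) * (exp((psi_D+psi_R)*t) - 1)

so the probability a culture is still transconjugant-free at t is
``p0(t) = exp(-Lambda(t))``.  Everything in this module is closed-form or
quadrature and serves as ground truth for the stochastic engines and the
estimators.

Units are fixed package-wide: time in hours, densities in cfu/ml,
conjugation rates in ml cell^-1 hr^-1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad, solve_ivp

from .errors import DomainError, IntegrationError, NoEventError

__all__ = [
    "RateParameters",
    "InoculumState",
    "DeterministicTrajectory",
    "ode_solve",
    "exponential_density",
    "p0_analytic",
    "cumulative_hazard",
    "mean_tstar_analytic",
]


@dataclass(frozen=True)
class RateParameters:
    """The five rate constants of the mating model.

    Attributes
    ----------
    psi_D, psi_R, psi_T:
        Per-capita growth rates of donors, recipients and transconjugants
        (hr^-1).
    gamma_D:
        Donor-to-recipient conjugation rate (ml cell^-1 hr^-1).
    gamma_T:
        Transconjugant-to-recipient conjugation rate (ml cell^-1 hr^-1).
    """

    psi_D: float
    psi_R: float
    psi_T: float
    gamma_D: float
    gamma_T: float

    def __post_init__(self) -> None:
        for name in ("psi_D", "psi_R", "psi_T", "gamma_D", "gamma_T"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise DomainError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def psi_sum(self) -> float:
        """psi_D + psi_R, the growth rate of the product D*R."""
        return self.psi_D + self.psi_R

    def replace(self, **kwargs) -> "RateParameters":
        d = self.to_dict()
        d.update(kwargs)
        return RateParameters(**d)

    def to_dict(self) -> dict:
        return {
            "psi_D": self.psi_D,
            "psi_R": self.psi_R,
            "psi_T": self.psi_T,
            "gamma_D": self.gamma_D,
            "gamma_T": self.gamma_T,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RateParameters":
        return cls(**{k: float(d[k]) for k in
                      ("psi_D", "psi_R", "psi_T", "gamma_D", "gamma_T")})


@dataclass(frozen=True)
class InoculumState:
    """Initial densities (cfu/ml) of the three populations."""

    D0: float
    R0: float
    T0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("D0", "R0", "T0"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise DomainError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def is_ldm_valid(self) -> bool:
        """True if the inoculum satisfies D0 > 0, R0 > 0, T0 = 0."""
        return self.D0 > 0 and self.R0 > 0 and self.T0 == 0

    def to_dict(self) -> dict:
        return {"D0": self.D0, "R0": self.R0, "T0": self.T0}

    @classmethod
    def from_dict(cls, d: dict) -> "InoculumState":
        return cls(float(d["D0"]), float(d["R0"]), float(d.get("T0", 0.0)))


@dataclass
class DeterministicTrajectory:
    """Densities on a time grid, as produced by :func:`ode_solve`."""

    times: np.ndarray
    D: np.ndarray
    R: np.ndarray
    T: np.ndarray
    N: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        if self.N is None:
            self.N = self.D + self.R + self.T
        else:
            self.N = np.asarray(self.N, dtype=float)

    def at(self, t: float) -> tuple[float, float, float]:
        """(D, R, T) at grid time ``t`` (must be on the grid)."""
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > 1e-9 * max(1.0, abs(t)):
            raise KeyError(f"time {t} is not on the trajectory grid")
        return float(self.D[i]), float(self.R[i]), float(self.T[i])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "D": self.D, "R": self.R,
             "T": self.T, "N": self.N}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _expm1_over_x(x: float) -> float:
    # (e^x - 1)/x, series-protected near 0 to avoid cancellation
    if abs(x) < 1e-8:
        return 1.0 + x / 2.0 + x * x / 6.0
    return math.expm1(x) / x


def exponential_density(x0: float, psi: float, t: float) -> float:
    """Closed-form exponential growth ``x0 * exp(psi*t)``.

    Overflow returns +inf with a warning rather than raising.
    """
    if x0 < 0:
        raise DomainError(f"density must be >= 0, got {x0}")
    if t < 0:
        raise DomainError(f"time must be >= 0, got {t}")
    if x0 == 0:
        return 0.0
    arg = psi * t
    if arg > 700:  # exp overflow threshold for float64
        warnings.warn(
            f"exponential_density overflow (psi*t = {arg:.3g}); returning inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.inf
    return x0 * math.exp(arg)


def cumulative_hazard(
    params: RateParameters,
    init: InoculumState,
    t,
    volume: float = 1.0,
):
    """Expected number of donor-to-recipient conjugation events by time t.

    For a culture of ``volume`` ml inoculated at densities ``D0``, ``R0``
    the whole-culture hazard rate at time s is
    ``gamma_D * D(s) * R(s) * volume`` (counts are density*volume and the
    mass-action propensity carries a 1/volume), giving

        Lambda(t) = volume * gamma_D * D0 * R0 * t * phi((psi_D+psi_R) t)

    with phi(x) = (e^x - 1)/x.  Accepts scalar or array ``t``.
    """
    if init.T0 != 0:
        raise DomainError(
            "the transconjugant-free probability assumes T0 = 0; "
            f"got T0 = {init.T0}"
        )
    if volume <= 0:
        raise DomainError(f"volume must be > 0, got {volume}")
    s = params.psi_sum
    rate0 = volume * params.gamma_D * init.D0 * init.R0

    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("time must be >= 0")
    phi = np.array(
        [_expm1_over_x(s * ti) for ti in np.atleast_1d(t_arr)]
    ).reshape(t_arr.shape)
    out = rate0 * t_arr * phi
    if out.ndim == 0:
        return float(out)
    return out


def p0_analytic(
    params: RateParameters,
    init: InoculumState,
    t,
    volume: float = 1.0,
):
    """Probability that a culture is transconjugant-free at time ``t``.

    ``p0(t) = exp(-Lambda(t))`` with the cumulative hazard above; equals 1
    at t = 0 and decreases in t, gamma_D, D0, R0 and volume.  The
    psi_D + psi_R = 0 case is handled by the analytic limit
    ``exp(-gamma_D*D0*R0*volume*t)``.
    """
    lam = cumulative_hazard(params, init, t, volume)
    if isinstance(lam, float):
        return math.exp(-lam)
    return np.exp(-lam)


def mean_tstar_analytic(
    params: RateParameters,
    init: InoculumState,
    volume: float = 1.0,
) -> float:
    """Expected time of the first donor-to-recipient conjugation event.

    E[t*] = integral_0^inf p0(t) dt, evaluated by adaptive quadrature and
    truncated where p0 drops below 1e-12.
    """
    rate0 = volume * params.gamma_D * init.D0 * init.R0
    if rate0 <= 0:
        raise NoEventError(
            "gamma_D * D0 * R0 = 0: the first-event hazard is identically "
            "zero and t* does not exist"
        )
    s = params.psi_sum
    L = -math.log(1e-12)  # truncate where Lambda(t) > ~27.6
    if s > 0:
        t_upper = math.log1p(s * L / rate0) / s
    else:
        t_upper = L / rate0
    val, _ = quad(
        lambda t: math.exp(-cumulative_hazard(params, init, t, volume)),
        0.0,
        t_upper,
        limit=200,
    )
    return float(val)


def ode_solve(
    params: RateParameters,
    init: InoculumState,
    times,
    rtol: float = 1e-10,
    atol: float = 1e-8,
) -> DeterministicTrajectory:
    """Integrate the full mating model on a strictly increasing time grid.

    The recipient loss terms ``-gamma_D*D*R - gamma_T*T*R`` are kept even
    though the first-event theory neglects them; the discrepancy is
    negligible whenever gamma*D << psi_R and is itself a testable property.

    Notes
    -----
    Transconjugant densities can span many orders of magnitude below the
    other populations, so the default absolute tolerance is small
    (1e-8 cfu/ml).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise DomainError("times must be a 1-d grid with at least 2 points")
    if times[0] != 0:
        raise DomainError(f"times[0] must be 0, got {times[0]}")
    if np.any(np.diff(times) <= 0):
        raise DomainError("times must be strictly increasing")

    p = params

    def rhs(_t, y):
        D, R, T = y
        conj_d = p.gamma_D * D * R
        conj_t = p.gamma_T * T * R
        return (
            p.psi_D * D,
            p.psi_R * R - conj_d - conj_t,
            p.psi_T * T + conj_d + conj_t,
        )

    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        [init.D0, init.R0, init.T0],
        method="DOP853",
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        t_reached = float(sol.t[-1]) if sol.t.size else 0.0
        raise IntegrationError(
            f"mating-model integration failed at t = {t_reached:.6g} hr: "
            f"{sol.message}",
            t_reached=t_reached,
        )
    D, R, T = sol.y
    return DeterministicTrajectory(times=times, D=D, R=R, T=T)
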