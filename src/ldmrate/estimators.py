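"""Conjugation-rate and mutation-rate estimators.

Four estimators are provided, all returning :class:`EstimateResult`:

* ``sim_estimate`` — the Simonsen et al. end-point estimate, which assumes
  identical growth and conjugation rates across the three populations:

      gamma_D = psi * ln(1 + (T/R) * (N/D)) / (N - N0)

  with all final densities read at the incubation time t~ and psi the
  realized growth rate of the total population.

* ``ldm_parametric`` — inverts the transconjugant-free probability
  p0(t~) = exp(-gamma_D*D0*R0/(psi_D+psi_R) * (e^((psi_D+psi_R) t~) - 1))
  for gamma_D, given known growth rates.

* ``ldm_endpoint`` — the laboratory form of the same estimate, using only
  measured initial/final donor and recipient densities:

      gamma_D = f * (-ln p0_hat) * (ln(Dt Rt) - ln(D0 R0))
                / (t~ * (Dt Rt - D0 R0))

  It is algebraically identical to ``ldm_parametric`` when psi_D and psi_R
  are replaced by the realized rates ln(Dt/D0)/t~ and ln(Rt/R0)/t~.

* ``ld_mutation_rate`` — the classical fluctuation-test mutation rate;
  conjugation maps onto it with wild-type size N0 -> D0*R0 and growth rate
  psi_N -> psi_D + psi_R.

``f`` is the reciprocal of the coculture volume in ml and scales the
1-ml-volume formulas linearly; every estimator is homogeneous of degree 1
in ``f``.  Degenerate observations produce flagged results with
machine-readable ``reason`` codes instead of raising, so that simulation
sweeps can count them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .core_model import InoculumState, RateParameters, _expm1_over_x
from .errors import DomainError

__all__ = [
    "AssayObservation",
    "EstimateResult",
    "growth_rate_realized",
    "sim_estimate",
    "p0_mle",
    "ldm_parametric",
    "ldm_endpoint",
    "ld_mutation_rate",
    "observations_from_csv",
    "results_to_dataframe",
]

# reason codes carried by EstimateResult
REASON_NO_TRANSCONJUGANTS = "no_transconjugants"
REASON_NO_WELLS_TURBID = "no_wells_turbid"
REASON_ALL_WELLS_TURBID = "all_wells_turbid"
REASON_NO_NET_GROWTH = "no_net_growth"
REASON_ZERO_POPULATION = "zero_donors_or_recipients"
REASON_DEGENERATE_GROWTH = "degenerate_growth"


@dataclass(frozen=True)
class AssayObservation:
    """The measured quantities of one mating assay.

    Densities are cfu/ml; ``f`` is the reciprocal culture volume (ml^-1);
    ``p0_hat`` is the observed fraction of transconjugant-free cocultures
    (with ``n_wells`` scored), present only for fluctuation-style assays.
    """

    t_tilde: float
    D0: float | None = None
    R0: float | None = None
    N0: float | None = None
    Dt: float | None = None
    Rt: float | None = None
    Tt: float | None = None
    Nt: float | None = None
    f: float = 1.0
    p0_hat: float | None = None
    n_wells: int | None = None

    def __post_init__(self) -> None:
        if self.t_tilde <= 0:
            raise DomainError(f"t_tilde must be > 0, got {self.t_tilde}")
        if self.f <= 0:
            raise DomainError(f"f must be > 0, got {self.f}")
        for name in ("D0", "R0", "N0", "Dt", "Rt", "Tt", "Nt"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise DomainError(f"{name} must be >= 0, got {v}")
        if self.p0_hat is not None and not 0.0 <= self.p0_hat <= 1.0:
            raise DomainError(f"p0_hat must be in [0, 1], got {self.p0_hat}")
        if None not in (self.Dt, self.Rt, self.Tt, self.Nt):
            total = self.Dt + self.Rt + self.Tt
            if self.Nt > 0 and abs(total - self.Nt) > 0.01 * self.Nt:
                raise DomainError(
                    f"Nt = {self.Nt} differs from Dt+Rt+Tt = {total} "
                    "by more than 1%"
                )

    def to_dict(self) -> dict:
        return {
            "t_tilde": self.t_tilde, "D0": self.D0, "R0": self.R0,
            "N0": self.N0, "Dt": self.Dt, "Rt": self.Rt, "Tt": self.Tt,
            "Nt": self.Nt, "f": self.f, "p0_hat": self.p0_hat,
            "n_wells": self.n_wells,
        }


@dataclass(frozen=True)
class EstimateResult:
    """One conjugation- (or mutation-) rate estimate.

    ``value`` is in ml cell^-1 hr^-1 (per-capita per unit time for the
    mutation analogue).  ``valid`` is False for degenerate inputs, with the
    cause in ``reason``; a valid zero (no transconjugants observed) keeps
    ``valid=True`` with an explanatory reason.
    """

    method: str
    value: float
    valid: bool
    reason: str | None = None
    inputs: dict = field(default_factory=dict)

    @property
    def is_finite_nonzero(self) -> bool:
        return self.valid and math.isfinite(self.value) and self.value > 0

    def to_dict(self) -> dict:
        d = {"method": self.method, "value": self.value,
             "valid": self.valid, "reason": self.reason}
        d.update({f"input_{k}": v for k, v in self.inputs.items()})
        return d


def growth_rate_realized(x0: float, xt: float, t: float) -> float:
    """Realized exponential growth rate ``ln(xt/x0)/t`` (hr^-1)."""
    if x0 <= 0 or xt <= 0:
        raise DomainError(
            f"densities must be > 0 to infer a growth rate, got {x0}, {xt}"
        )
    if t <= 0:
        raise DomainError(f"t must be > 0, got {t}")
    return math.log(xt / x0) / t


def sim_estimate(obs: AssayObservation, psi: float | None = None
                 ) -> EstimateResult:
    """End-point estimate assuming identical growth and conjugation rates.

    ``psi`` defaults to the realized total-population growth rate
    ``ln(Nt/N0)/t~`` but can be overridden.
    """
    needed = (obs.N0, obs.Nt, obs.Dt, obs.Rt, obs.Tt)
    if any(v is None for v in needed):
        raise DomainError(
            "sim_estimate needs N0, Nt, Dt, Rt and Tt in the observation"
        )
    if obs.Dt <= 0 or obs.Rt <= 0:
        return EstimateResult("SIM", math.nan, False,
                              REASON_ZERO_POPULATION, obs.to_dict())
    if obs.Nt <= obs.N0 or obs.N0 <= 0:
        return EstimateResult("SIM", math.nan, False,
                              REASON_NO_NET_GROWTH, obs.to_dict())
    if obs.Tt == 0:
        return EstimateResult("SIM", 0.0, True,
                              REASON_NO_TRANSCONJUGANTS, obs.to_dict())
    if psi is None:
        psi = growth_rate_realized(obs.N0, obs.Nt, obs.t_tilde)
    value = (psi * math.log1p((obs.Tt / obs.Rt) * (obs.Nt / obs.Dt))
             / (obs.Nt - obs.N0))
    return EstimateResult("SIM", value, True, None, obs.to_dict())


def p0_mle(n_negative: int, n_total: int) -> float:
    """Maximum-likelihood estimate of the transconjugant-free probability.

    Simply the fraction of scored cocultures without transconjugants.
    """
    if n_total < 1:
        raise DomainError(f"n_total must be >= 1, got {n_total}")
    if not 0 <= n_negative <= n_total:
        raise DomainError(
            f"n_negative must be in [0, {n_total}], got {n_negative}"
        )
    return n_negative / n_total


def _ldm_rate_from_p0(p0_hat: float, s: float, product0: float,
                      t_tilde: float, f: float, correction: float) -> float:
    # gamma_D = f * (-ln p0) * s / (product0 * (e^(s t) - 1)); the
    # series-protected phi(x) = (e^x - 1)/x keeps the s -> 0 limit exact
    lam = -math.log(p0_hat)
    return correction * f * lam / (product0 * t_tilde
                                   * _expm1_over_x(s * t_tilde))


def ldm_parametric(
    p0_hat: float,
    params: RateParameters,
    init: InoculumState,
    t_tilde: float,
    f: float = 1.0,
    correction: float = 1.0,
) -> EstimateResult:
    """Invert the transconjugant-free probability for gamma_D.

    Uses the known growth rates psi_D and psi_R from ``params``.
    ``correction`` is a multiplicative hook (default 1) for establishment-
    probability adjustments.
    """
    if not 0.0 <= p0_hat <= 1.0:
        raise DomainError(f"p0_hat must be in [0, 1], got {p0_hat}")
    if t_tilde <= 0:
        raise DomainError(f"t_tilde must be > 0, got {t_tilde}")
    if init.D0 * init.R0 <= 0:
        raise DomainError("D0 * R0 must be > 0")
    inputs = {"p0_hat": p0_hat, "t_tilde": t_tilde, "f": f,
              "D0": init.D0, "R0": init.R0,
              "psi_D": params.psi_D, "psi_R": params.psi_R}
    if p0_hat == 1.0:
        return EstimateResult("LDM-parametric", 0.0, True,
                              REASON_NO_WELLS_TURBID, inputs)
    if p0_hat == 0.0:
        return EstimateResult("LDM-parametric", math.nan, False,
                              REASON_ALL_WELLS_TURBID, inputs)
    value = _ldm_rate_from_p0(p0_hat, params.psi_sum, init.D0 * init.R0,
                              t_tilde, f, correction)
    return EstimateResult("LDM-parametric", value, True, None, inputs)


def ldm_endpoint(obs: AssayObservation,
                 correction: float = 1.0) -> EstimateResult:
    """Laboratory end-point form of the fluctuation estimate.

    gamma_D = f * (-ln p0_hat) * (ln(Dt*Rt) - ln(D0*R0))
              / (t~ * (Dt*Rt - D0*R0))

    which equals :func:`ldm_parametric` with the realized growth rates
    substituted for psi_D and psi_R.
    """
    needed = (obs.p0_hat, obs.D0, obs.R0, obs.Dt, obs.Rt)
    if any(v is None for v in needed):
        raise DomainError(
            "ldm_endpoint needs p0_hat, D0, R0, Dt and Rt in the observation"
        )
    if min(obs.D0, obs.R0, obs.Dt, obs.Rt) <= 0:
        return EstimateResult("LDM", math.nan, False,
                              REASON_ZERO_POPULATION, obs.to_dict())
    if obs.p0_hat == 1.0:
        return EstimateResult("LDM", 0.0, True,
                              REASON_NO_WELLS_TURBID, obs.to_dict())
    if obs.p0_hat == 0.0:
        return EstimateResult("LDM", math.nan, False,
                              REASON_ALL_WELLS_TURBID, obs.to_dict())
    prod0 = obs.D0 * obs.R0
    prodt = obs.Dt * obs.Rt
    if prodt == prod0:
        return EstimateResult("LDM", math.nan, False,
                              REASON_DEGENERATE_GROWTH, obs.to_dict())
    # write as the parametric form with realized rates so that the s -> 0
    # (no-growth) limit is handled by the same series-protected phi
    s_real = math.log(prodt / prod0) / obs.t_tilde
    value = _ldm_rate_from_p0(obs.p0_hat, s_real, prod0, obs.t_tilde,
                              obs.f, correction)
    return EstimateResult("LDM", value, True, None, obs.to_dict())


def ld_mutation_rate(
    p0_hat: float,
    N0: float,
    psi_N: float,
    t_tilde: float,
    correction: float = 1.0,
) -> EstimateResult:
    """Classical fluctuation-test mutation rate from the zero-mutant
    fraction.

    mu = (-ln p0_hat) * psi_N / (N0 * (e^(psi_N t~) - 1))

    Conjugation is the special case N0 -> D0*R0, psi_N -> psi_D + psi_R.
    """
    if not 0.0 <= p0_hat <= 1.0:
        raise DomainError(f"p0_hat must be in [0, 1], got {p0_hat}")
    if N0 <= 0:
        raise DomainError(f"N0 must be > 0, got {N0}")
    if t_tilde <= 0:
        raise DomainError(f"t_tilde must be > 0, got {t_tilde}")
    inputs = {"p0_hat": p0_hat, "N0": N0, "psi_N": psi_N,
              "t_tilde": t_tilde}
    if p0_hat == 1.0:
        return EstimateResult("LD-mutation", 0.0, True,
                              REASON_NO_WELLS_TURBID, inputs)
    if p0_hat == 0.0:
        return EstimateResult("LD-mutation", math.nan, False,
                              REASON_ALL_WELLS_TURBID, inputs)
    value = _ldm_rate_from_p0(p0_hat, psi_N, N0, t_tilde, 1.0, correction)
    return EstimateResult("LD-mutation", value, True, None, inputs)


def observations_from_csv(path) -> list[AssayObservation]:
    """Read assay observations from a tidy CSV (one row per assay)."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        for name in ("t_tilde", "D0", "R0", "N0", "Dt", "Rt", "Tt", "Nt",
                     "f", "p0_hat", "n_wells"):
            if name in df.columns and pd.notna(row[name]):
                kwargs[name] = (int(row[name]) if name == "n_wells"
                                else float(row[name]))
        out.append(AssayObservation(**kwargs))
    return out


def results_to_dataframe(results: list[EstimateResult]) -> pd.DataFrame:
    """Tidy table of estimates: method, value, validity, reason, inputs."""
    return pd.DataFrame([r.to_dict() for r in results])
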