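"""Laboratory-facing layer: microtiter-plate records and plate estimates.

A fluctuation plate is a 96-well (deep-well) plate: 84 cocultures scored
turbid/nonturbid after growth under transconjugant-selecting medium, a few
cocultures sampled by dilution plating for initial and final donor and
recipient densities, and control wells — donor and recipient monocultures
(must stay nonturbid under selection), a transconjugant monoculture (must
grow), and donor+recipient mixes created at the end of the incubation
(must stay nonturbid, proving that selection suppresses further
conjugation).  The nonturbid fraction of the cocultures is the
maximum-likelihood estimate of the transconjugant-free probability, and
one plate yields one fluctuation (LDM) estimate of the donor conjugation
rate.

Plate CSV dialect
-----------------
Leading comment lines carry plate metadata::

    # culture_volume_ml=0.1
    # t_tilde_hr=3.5

followed by a header row and one row per well, plus one extra row per
dilution-plating record (same ``well_id``)::

    well_id,role,turbid,target,timepoint,colony_count,dilution_factor,plated_volume_ml

Roles: ``coculture``, ``density-coculture``, ``donor-control``,
``recipient-control``, ``transconjugant-control``, ``mixed-control``,
``blank``.  Coculture wells require a turbidity call.  Parsing collects
every violation with its line number before raising.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import (
    InoculumState,
    RateParameters,
    exponential_density,
    p0_analytic,
)
from .errors import DomainError, PlateParseError
from .estimators import (
    AssayObservation,
    EstimateResult,
    ldm_endpoint,
    p0_mle,
    sim_estimate,
)

__all__ = [
    "WellRecord",
    "PlatingRecord",
    "PlateData",
    "ControlReport",
    "PlateEstimate",
    "parse_plate",
    "write_plate",
    "validate_controls",
    "cfu_density",
    "plate_ldm_estimate",
    "plate_sim_estimate",
    "generate_plate_fixture",
]

ROLES = frozenset({
    "coculture", "density-coculture", "donor-control", "recipient-control",
    "transconjugant-control", "mixed-control", "blank",
})
TARGETS = frozenset({
    "donor-selective", "recipient-selective", "transconjugant-selective",
})
TIMEPOINTS = frozenset({"initial", "final"})

_COLUMNS = ["well_id", "role", "turbid", "target", "timepoint",
            "colony_count", "dilution_factor", "plated_volume_ml"]


@dataclass
class PlatingRecord:
    """One dilution-plating measurement from a well."""

    target: str
    timepoint: str
    colony_count: int
    dilution_factor: float
    plated_volume_ml: float

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise DomainError(f"unknown plating target {self.target!r}")
        if self.timepoint not in TIMEPOINTS:
            raise DomainError(f"unknown timepoint {self.timepoint!r}")
        if self.colony_count < 0:
            raise DomainError("colony_count must be >= 0")
        if self.dilution_factor < 1:
            raise DomainError("dilution_factor must be >= 1")
        if self.plated_volume_ml <= 0:
            raise DomainError("plated_volume_ml must be > 0")


@dataclass
class WellRecord:
    """One well: its role, turbidity call, and any plating records."""

    well_id: str
    role: str
    turbid: bool | None = None
    platings: list[PlatingRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise DomainError(f"unknown well role {self.role!r}")


@dataclass
class PlateData:
    """One microtiter plate's worth of records."""

    wells: list[WellRecord]
    culture_volume_ml: float
    t_tilde: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.culture_volume_ml <= 0:
            raise DomainError("culture_volume_ml must be > 0")
        if self.t_tilde <= 0:
            raise DomainError("t_tilde must be > 0")

    @property
    def f(self) -> float:
        """Volume correction: reciprocal of the coculture volume in ml."""
        return 1.0 / self.culture_volume_ml

    def wells_by_role(self, role: str) -> list[WellRecord]:
        return [w for w in self.wells if w.role == role]

    def role_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for w in self.wells:
            out[w.role] = out.get(w.role, 0) + 1
        return out


def cfu_density(rec: PlatingRecord) -> float:
    """Standard dilution-plating arithmetic, in cfu/ml.

    density = colony_count * dilution_factor / plated_volume_ml
    """
    return rec.colony_count * rec.dilution_factor / rec.plated_volume_ml


# ---------------------------------------------------------------------------
# parsing / writing


def parse_plate(file) -> PlateData:
    """Parse a plate CSV (path or file-like) into a validated PlateData."""
    if hasattr(file, "read"):
        text = file.read()
    else:
        with open(file, encoding="utf-8") as fh:
            text = fh.read()
    meta: dict[str, str] = {}
    body_lines: list[tuple[int, str]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("#"):
            if "=" in line:
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
        elif line.strip():
            body_lines.append((lineno, line))

    violations: list[str] = []
    try:
        volume = float(meta["culture_volume_ml"])
    except (KeyError, ValueError):
        violations.append("missing or invalid '# culture_volume_ml=' header")
        volume = math.nan
    try:
        t_tilde = float(meta["t_tilde_hr"])
    except (KeyError, ValueError):
        violations.append("missing or invalid '# t_tilde_hr=' header")
        t_tilde = math.nan

    if not body_lines:
        raise PlateParseError(violations + ["no well rows found"])
    df = pd.read_csv(io.StringIO("\n".join(l for _, l in body_lines)))
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise PlateParseError(
            violations + [f"missing columns: {', '.join(missing)}"]
        )
    # line numbers of data rows in the original file (header is first body
    # line)
    data_linenos = [n for n, _ in body_lines[1:]]

    wells: dict[str, WellRecord] = {}
    for i, row in df.iterrows():
        lineno = data_linenos[i] if i < len(data_linenos) else -1
        wid = str(row["well_id"])
        role = str(row["role"])
        if role not in ROLES:
            violations.append(f"line {lineno}: unknown role {role!r}")
            continue
        turbid = None
        if pd.notna(row["turbid"]):
            turbid = str(row["turbid"]).strip().lower() in ("true", "1",
                                                            "yes")
        has_plating = pd.notna(row["target"])
        if wid in wells:
            w = wells[wid]
            if not has_plating:
                violations.append(f"line {lineno}: duplicate well {wid}")
                continue
            if w.role != role:
                violations.append(
                    f"line {lineno}: well {wid} re-declared with role "
                    f"{role!r} (was {w.role!r})"
                )
                continue
        else:
            w = WellRecord(well_id=wid, role=role, turbid=turbid)
            wells[wid] = w
        if has_plating:
            try:
                w.platings.append(PlatingRecord(
                    target=str(row["target"]),
                    timepoint=str(row["timepoint"]),
                    colony_count=int(row["colony_count"]),
                    dilution_factor=float(row["dilution_factor"]),
                    plated_volume_ml=float(row["plated_volume_ml"]),
                ))
            except (DomainError, ValueError) as exc:
                violations.append(f"line {lineno}: {exc}")

    for w in wells.values():
        if w.role == "coculture" and w.turbid is None:
            violations.append(
                f"coculture well {w.well_id} is missing a turbidity call"
            )
    if not any(w.role == "coculture" for w in wells.values()):
        violations.append("plate has no coculture wells")
    if violations:
        raise PlateParseError(violations)
    return PlateData(
        wells=list(wells.values()), culture_volume_ml=volume,
        t_tilde=t_tilde,
        metadata={k: v for k, v in meta.items()
                  if k not in ("culture_volume_ml", "t_tilde_hr")},
    )


def write_plate(plate: PlateData, file) -> None:
    """Write a plate back to the documented CSV dialect (lossless)."""
    rows = []
    for w in plate.wells:
        base = {"well_id": w.well_id, "role": w.role,
                "turbid": "" if w.turbid is None else str(w.turbid)}
        if not w.platings:
            rows.append({**base, "target": "", "timepoint": "",
                         "colony_count": "", "dilution_factor": "",
                         "plated_volume_ml": ""})
        for rec in w.platings:
            rows.append({**base, "target": rec.target,
                         "timepoint": rec.timepoint,
                         "colony_count": rec.colony_count,
                         "dilution_factor": rec.dilution_factor,
                         "plated_volume_ml": rec.plated_volume_ml})
    header = [f"# culture_volume_ml={plate.culture_volume_ml}",
              f"# t_tilde_hr={plate.t_tilde}"]
    header += [f"# {k}={v}" for k, v in plate.metadata.items()]
    body = pd.DataFrame(rows, columns=_COLUMNS).to_csv(index=False)
    text = "\n".join(header) + "\n" + body
    if hasattr(file, "write"):
        file.write(text)
    else:
        with open(file, "w", encoding="utf-8") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# controls


@dataclass
class ControlReport:
    """Pass/fail per control class; failures leave the estimate untrusted."""

    checks: dict[str, str]  # class -> "pass" | "fail: ..." | "missing"
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(v.startswith("fail") for v in self.checks.values())


def validate_controls(plate: PlateData) -> ControlReport:
    """Check the expected turbidity of each control class.

    Donor and recipient monocultures must be nonturbid under selection
    (counterselection works), the transconjugant monoculture must be
    turbid (selection is not too strong), and the end-of-assay
    donor+recipient mixes must be nonturbid (selection suppresses further
    conjugation).
    """
    expectations = {
        "donor-control": (False, "donor grows under selection — "
                                 "counterselection failed"),
        "recipient-control": (False, "recipient grows under selection — "
                                     "counterselection failed"),
        "transconjugant-control": (True, "transconjugant fails to grow — "
                                         "selection too strong"),
        "mixed-control": (False, "conjugation under selection not "
                                 "suppressed"),
    }
    checks: dict[str, str] = {}
    warnings: list[str] = []
    for role, (want_turbid, fail_msg) in expectations.items():
        found = plate.wells_by_role(role)
        if not found:
            checks[role] = "missing"
            warnings.append(f"no {role} wells on the plate")
            continue
        bad = [w.well_id for w in found
               if w.turbid is not None and w.turbid != want_turbid]
        checks[role] = f"fail: {fail_msg} ({', '.join(bad)})" if bad \
            else "pass"
    return ControlReport(checks=checks, warnings=warnings)


# ---------------------------------------------------------------------------
# estimates


def _mean_density(plate: PlateData, target: str, timepoint: str) -> float:
    vals = [cfu_density(rec)
            for w in plate.wells_by_role("density-coculture")
            for rec in w.platings
            if rec.target == target and rec.timepoint == timepoint]
    if not vals:
        raise DomainError(
            f"no density-coculture plating for {target} at {timepoint}"
        )
    # linear-scale average over replicate wells
    return float(np.mean(vals))


@dataclass
class PlateEstimate:
    """A plate-level estimate bundled with its control report."""

    estimate: EstimateResult
    controls: ControlReport
    p0_hat: float | None = None
    n_cocultures: int | None = None

    @property
    def trusted(self) -> bool:
        return self.controls.ok and self.estimate.valid


def plate_ldm_estimate(plate: PlateData) -> PlateEstimate:
    """One fluctuation (LDM) estimate from one plate.

    ``p0_hat`` is the nonturbid fraction of the coculture wells; densities
    are linear-scale means over the density wells; f = 1/culture volume.
    Control failures flag the result untrusted but do not block it.
    """
    cocultures = plate.wells_by_role("coculture")
    if not cocultures:
        raise DomainError("plate has no coculture wells")
    n_neg = sum(1 for w in cocultures if not w.turbid)
    p0_hat = p0_mle(n_neg, len(cocultures))
    obs = AssayObservation(
        t_tilde=plate.t_tilde,
        D0=_mean_density(plate, "donor-selective", "initial"),
        R0=_mean_density(plate, "recipient-selective", "initial"),
        Dt=_mean_density(plate, "donor-selective", "final"),
        Rt=_mean_density(plate, "recipient-selective", "final"),
        f=plate.f, p0_hat=p0_hat, n_wells=len(cocultures),
    )
    return PlateEstimate(
        estimate=ldm_endpoint(obs), controls=validate_controls(plate),
        p0_hat=p0_hat, n_cocultures=len(cocultures),
    )


def plate_sim_estimate(plate: PlateData) -> PlateEstimate:
    """End-point (SIM) estimate from a plate's dilution platings.

    Requires transconjugant-selective platings at the final timepoint.
    """
    try:
        Tt = _mean_density(plate, "transconjugant-selective", "final")
    except DomainError as exc:
        raise DomainError(
            "SIM estimate needs transconjugant-selective platings: "
            f"{exc}"
        ) from exc
    D0 = _mean_density(plate, "donor-selective", "initial")
    R0 = _mean_density(plate, "recipient-selective", "initial")
    Dt = _mean_density(plate, "donor-selective", "final")
    Rt = _mean_density(plate, "recipient-selective", "final")
    obs = AssayObservation(
        t_tilde=plate.t_tilde, D0=D0, R0=R0, N0=D0 + R0,
        Dt=Dt, Rt=Rt, Tt=Tt, Nt=Dt + Rt + Tt, f=plate.f,
    )
    return PlateEstimate(
        estimate=sim_estimate(obs), controls=validate_controls(plate),
    )


# ---------------------------------------------------------------------------
# synthetic fixtures


def _auto_dilution(expected_density: float, plated_volume_ml: float,
                   target_colonies: float) -> float:
    """Power-of-ten dilution aiming near the target colony count."""
    raw = expected_density * plated_volume_ml
    if raw <= target_colonies:
        return 1.0
    return float(10 ** math.ceil(math.log10(raw / target_colonies)))


def generate_plate_fixture(
    params: RateParameters,
    init: InoculumState,
    t_tilde: float,
    culture_volume_ml: float = 0.1,
    seed: int = 0,
    n_cocultures: int = 84,
    n_density_wells: int = 3,
    plated_volume_ml: float = 0.1,
    target_colonies: float = 150.0,
) -> PlateData:
    """Generate a synthetic fluctuation plate under the branching model.

    Coculture turbidity is Bernoulli with success probability
    ``1 - p0(t~)`` evaluated at the well volume (halving the volume raises
    the transconjugant-free probability).  Density wells receive Poisson
    colony counts around the deterministic exponential expectations, with
    a power-of-ten dilution chosen to land near ``target_colonies``
    colonies.  Control wells are emitted in their expected states.  A
    single transconjugant is assumed to always render its well turbid
    (no establishment failure).
    """
    if init.T0 != 0:
        raise DomainError("plate fixtures assume T0 = 0")
    rng = np.random.default_rng(seed)
    p0 = p0_analytic(params, init, t_tilde, volume=culture_volume_ml)

    def _well_ids():
        for row in "ABCDEFGH":
            for col in range(1, 13):
                yield f"{row}{col}"

    ids = _well_ids()
    wells: list[WellRecord] = []
    for role in ("donor-control", "recipient-control",
                 "transconjugant-control"):
        wells.append(WellRecord(next(ids), role,
                                turbid=role == "transconjugant-control"))
    for _ in range(2):
        wells.append(WellRecord(next(ids), "mixed-control", turbid=False))

    expected = {
        ("donor-selective", "initial"): init.D0,
        ("recipient-selective", "initial"): init.R0,
        ("donor-selective", "final"):
            exponential_density(init.D0, params.psi_D, t_tilde),
        ("recipient-selective", "final"):
            exponential_density(init.R0, params.psi_R, t_tilde),
    }
    for _ in range(n_density_wells):
        w = WellRecord(next(ids), "density-coculture")
        for (target, timepoint), dens in expected.items():
            dilution = _auto_dilution(dens, plated_volume_ml,
                                      target_colonies)
            mean_count = dens * plated_volume_ml / dilution
            if mean_count > 1e4:
                raise DomainError(
                    f"expected {mean_count:.3g} colonies for {target} at "
                    f"{timepoint}: increase dilution"
                )
            w.platings.append(PlatingRecord(
                target=target, timepoint=timepoint,
                colony_count=int(rng.poisson(mean_count)),
                dilution_factor=dilution,
                plated_volume_ml=plated_volume_ml,
            ))
        wells.append(w)

    turbid_draws = rng.random(n_cocultures) < (1.0 - p0)
    for turbid in turbid_draws:
        wells.append(WellRecord(next(ids), "coculture", turbid=bool(turbid)))
    for wid in ids:
        wells.append(WellRecord(wid, "blank"))

    return PlateData(
        wells=wells, culture_volume_ml=culture_volume_ml, t_tilde=t_tilde,
        metadata={"generator": "ldmrate synthetic fixture",
                  "seed": str(seed)},
    )
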