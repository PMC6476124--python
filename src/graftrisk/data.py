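"""Data model, CSV input/validation, and fitted-model (de)serialization.

The package works on two tables:

* a long table of serum-creatinine measurements
  (``subject_id, time_years, scr_umol_l``), time measured in years since
  transplantation;
* a one-row-per-subject table of covariates and the survival outcome
  (``subject_id, donor_age, ndsa_pre, proteinuria_m12, acute_rejection,
  ar_time, dndsa, dndsa_time, entry_time, event_time, event``).

Graft failure (return to dialysis or preemptive retransplantation) is the
event; death with a functioning graft counts as censoring.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd

from .links import LinkSpec

logger = logging.getLogger(__name__)

#: month-12 proteinuria dichotomization threshold (g/L)
PROTEINURIA_THRESHOLD = 0.275

#: order of the hazard covariate vector used throughout the package
HAZARD_COVARIATES = (
    "ndsa_pre",
    "prot_gt_0275",
    "dndsa",
    "acute_rejection",
    "dndsa_x_ar",
)

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """A required column is missing or a document is malformed."""


class ValidationError(ValueError):
    """Input rows violate a typed invariant; message lists offenders."""


@dataclass(frozen=True)
class LongitudinalRecord:
    """One serum-creatinine measurement."""

    subject_id: str
    t: float  # years since transplantation, >= 0
    y: float  # serum creatinine, µmol/L, > 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.t) or self.t < 0:
            raise ValidationError(
                f"subject {self.subject_id}: time {self.t!r} must be finite and >= 0"
            )
        if not math.isfinite(self.y) or self.y <= 0:
            raise ValidationError(
                f"subject {self.subject_id}: creatinine {self.y!r} must be > 0"
            )


@dataclass(frozen=True)
class SubjectProfile:
    """Baseline covariates and survival outcome for one subject.

    ``event=1`` is graft failure; ``event=0`` covers administrative
    censoring and death with a functioning graft alike.
    """

    subject_id: str
    donor_age_ge60: int
    ndsa_pre: int
    proteinuria_m12: Optional[float]
    prot_gt_0275: int
    acute_rejection: int
    ar_time: Optional[float]
    dndsa: int
    dndsa_time: Optional[float]
    entry_time: float
    event_time: float
    event: int

    def __post_init__(self) -> None:
        sid = self.subject_id
        if self.event_time <= self.entry_time:
            raise ValidationError(
                f"subject {sid}: event_time {self.event_time} must exceed "
                f"entry_time {self.entry_time}"
            )
        if self.entry_time < 0:
            raise ValidationError(f"subject {sid}: entry_time must be >= 0")
        if bool(self.dndsa) != (self.dndsa_time is not None):
            raise ValidationError(
                f"subject {sid}: dndsa_time must be present iff dndsa=1"
            )
        if self.proteinuria_m12 is not None:
            if self.proteinuria_m12 < 0:
                raise ValidationError(f"subject {sid}: proteinuria must be >= 0")
            expected = int(self.proteinuria_m12 > PROTEINURIA_THRESHOLD)
            if self.prot_gt_0275 != expected:
                raise ValidationError(
                    f"subject {sid}: prot_gt_0275={self.prot_gt_0275} inconsistent "
                    f"with proteinuria_m12={self.proteinuria_m12}"
                )

    def hazard_covariates(self) -> np.ndarray:
        """Hazard design vector in :data:`HAZARD_COVARIATES` order."""
        return np.array(
            [
                self.ndsa_pre,
                self.prot_gt_0275,
                self.dndsa,
                self.acute_rejection,
                self.dndsa * self.acute_rejection,
            ],
            dtype=float,
        )

    def membership_covariates(self) -> np.ndarray:
        """Class-membership design vector (donor age >= 60 only)."""
        return np.array([self.donor_age_ge60], dtype=float)


@dataclass
class Cohort:
    """A validated set of subjects with their creatinine measurements."""

    subjects: list[SubjectProfile]
    measurements: pd.DataFrame  # columns: subject_id, t, y

    def __post_init__(self) -> None:
        need = {"subject_id", "t", "y"}
        if not need.issubset(self.measurements.columns):
            raise SchemaError(f"measurement frame needs columns {sorted(need)}")
        ids = {s.subject_id for s in self.subjects}
        meas_ids = set(self.measurements["subject_id"].astype(str))
        orphans = meas_ids - ids
        if orphans:
            raise ValidationError(
                f"measurements reference unknown subjects: {sorted(orphans)[:5]}"
            )
        missing = ids - meas_ids
        if missing:
            raise ValidationError(
                f"subjects without any measurement: {sorted(missing)[:5]}"
            )
        dup = self.measurements.duplicated(subset=["subject_id", "t"])
        if dup.any():
            bad = self.measurements.loc[dup, ["subject_id", "t"]]
            raise ValidationError(
                f"duplicate (subject, time) measurement rows: {bad.head().to_dict('records')}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def subject(self, subject_id: str) -> SubjectProfile:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def measurements_for(self, subject_id: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.measurements[self.measurements["subject_id"] == subject_id]
        m = m.sort_values("t")
        return m["t"].to_numpy(float), m["y"].to_numpy(float)

    def subset(self, subject_ids: Sequence[str]) -> "Cohort":
        keep = set(map(str, subject_ids))
        subs = [s for s in self.subjects if s.subject_id in keep]
        meas = self.measurements[
            self.measurements["subject_id"].astype(str).isin(keep)
        ].reset_index(drop=True)
        return Cohort(subs, meas)


@dataclass
class ReadConfig:
    """Options for :func:`read_cohort`.

    min_followup applies the cohort inclusion rule (years of follow-up a
    subject must have). With ``delayed_entry=False`` short-followup
    subjects are dropped (inclusion filter); with ``True`` entry_time is
    kept and the survival likelihood conditions on it (left truncation).
    """

    min_followup: float = 1.0
    enforce_min_followup: bool = True
    delayed_entry: bool = False


LONG_COLUMNS = ["subject_id", "time_years", "scr_umol_l"]
SUBJECT_COLUMNS = [
    "subject_id",
    "donor_age",
    "ndsa_pre",
    "proteinuria_m12",
    "acute_rejection",
    "ar_time",
    "dndsa",
    "dndsa_time",
    "entry_time",
    "event_time",
    "event",
]


def _optional_float(v: Any) -> Optional[float]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or pd.isna(v):
        return None
    return float(v)


def subject_from_row(row: dict[str, Any]) -> SubjectProfile:
    """Build a validated SubjectProfile from one subject-table row.

    ``donor_age`` may be the age in years (dichotomized at 60) or an
    already-dichotomized 0/1 flag.
    """
    age = float(row["donor_age"])
    donor_ge60 = int(age >= 60) if age > 1 else int(age)
    prot = _optional_float(row.get("proteinuria_m12"))
    if prot is None:
        alt = _optional_float(row.get("proteinuria_m12_m18"))
        if alt is not None:
            prot = alt
        else:
            logger.warning(
                "subject %s: proteinuria at M12 missing and no M12-M18 fallback; "
                "dichotomized covariate imputed to 0",
                row["subject_id"],
            )
    prot_flag = int(prot is not None and prot > PROTEINURIA_THRESHOLD)
    return SubjectProfile(
        subject_id=str(row["subject_id"]),
        donor_age_ge60=donor_ge60,
        ndsa_pre=int(row["ndsa_pre"]),
        proteinuria_m12=prot,
        prot_gt_0275=prot_flag,
        acute_rejection=int(row["acute_rejection"]),
        ar_time=_optional_float(row.get("ar_time")),
        dndsa=int(row["dndsa"]),
        dndsa_time=_optional_float(row.get("dndsa_time")),
        entry_time=float(row.get("entry_time", 0.0) or 0.0),
        event_time=float(row["event_time"]),
        event=int(row["event"]),
    )


def read_cohort(
    long_csv_path: str,
    subject_csv_path: str,
    config: ReadConfig | None = None,
) -> Cohort:
    """Read and validate the two CSV inputs into a :class:`Cohort`.

    Rows violating invariants raise :class:`ValidationError` with the
    offending rows listed; nothing is silently dropped (the min-followup
    inclusion filter, when enabled, is the one documented exception and
    is logged per subject).
    """
    config = config or ReadConfig()
    long_df = pd.read_csv(long_csv_path)
    subj_df = pd.read_csv(subject_csv_path)
    missing = [c for c in LONG_COLUMNS if c not in long_df.columns]
    if missing:
        raise SchemaError(f"{long_csv_path}: missing columns {missing}")
    missing = [c for c in SUBJECT_COLUMNS if c not in subj_df.columns]
    if missing:
        raise SchemaError(f"{subject_csv_path}: missing columns {missing}")

    bad = long_df[~(long_df["scr_umol_l"] > 0)]
    if len(bad):
        raise ValidationError(
            f"non-positive creatinine in rows: {bad.index.tolist()[:10]}"
        )
    bad = long_df[~np.isfinite(long_df["time_years"]) | (long_df["time_years"] < 0)]
    if len(bad):
        raise ValidationError(f"invalid measurement times in rows: {bad.index.tolist()[:10]}")

    subjects = [subject_from_row(r) for r in subj_df.to_dict("records")]

    if config.enforce_min_followup and not config.delayed_entry:
        kept = []
        for s in subjects:
            if s.event_time - s.entry_time >= config.min_followup:
                kept.append(s)
            else:
                logger.warning(
                    "subject %s excluded: follow-up %.3f y below the %.2f y inclusion rule",
                    s.subject_id, s.event_time - s.entry_time, config.min_followup,
                )
        subjects = kept

    keep_ids = {s.subject_id for s in subjects}
    meas = long_df.rename(
        columns={"time_years": "t", "scr_umol_l": "y"}
    )[["subject_id", "t", "y"]].copy()
    meas["subject_id"] = meas["subject_id"].astype(str)
    meas = meas[meas["subject_id"].isin(keep_ids)].reset_index(drop=True)
    return Cohort(subjects, meas)


def write_cohort(cohort: Cohort, long_csv_path: str, subject_csv_path: str) -> None:
    """Write a cohort back to the two CSV formats read by :func:`read_cohort`."""
    meas = cohort.measurements.rename(columns={"t": "time_years", "y": "scr_umol_l"})
    meas.to_csv(long_csv_path, index=False)
    rows = []
    for s in cohort.subjects:
        rows.append(
            {
                "subject_id": s.subject_id,
                "donor_age": s.donor_age_ge60,
                "ndsa_pre": s.ndsa_pre,
                "proteinuria_m12": s.proteinuria_m12,
                "acute_rejection": s.acute_rejection,
                "ar_time": s.ar_time,
                "dndsa": s.dndsa,
                "dndsa_time": s.dndsa_time,
                "entry_time": s.entry_time,
                "event_time": s.event_time,
                "event": s.event,
            }
        )
    pd.DataFrame(rows).to_csv(subject_csv_path, index=False)


# ---------------------------------------------------------------------------
# model parameters and fit results
# ---------------------------------------------------------------------------


@dataclass
class JointModelParams:
    """Full parameter set of the joint latent class model.

    xi      -- (G-1, 1+K_m) multinomial membership coefficients, last class
               is the reference (all zeros, not stored)
    beta    -- (G, 3) class-specific fixed effects on the latent scale
               (intercept, linear, quadratic in time)
    B       -- (2, 2) PSD covariance of the random intercept and slope
    sigma   -- residual SD on the transformed scale (fixed to 1 at fit time
               for identifiability)
    link    -- monotone transformation between creatinine and the latent
               Gaussian scale
    zeta    -- (G, 2) Weibull baseline parameters per class, both > 0;
               cumulative hazard (zeta1 * t) ** zeta2
    delta   -- (5,) proportional-hazard coefficients shared across classes,
               in :data:`HAZARD_COVARIATES` order
    """

    n_classes: int
    xi: np.ndarray
    beta: np.ndarray
    B: np.ndarray
    sigma: float
    link: LinkSpec
    zeta: np.ndarray
    delta: np.ndarray

    def __post_init__(self) -> None:
        G = self.n_classes
        self.xi = np.atleast_2d(np.asarray(self.xi, float))
        if G == 1:
            self.xi = self.xi.reshape(0, self.xi.shape[-1] if self.xi.size else 1)
        self.beta = np.asarray(self.beta, float).reshape(G, -1)
        self.B = np.asarray(self.B, float)
        self.zeta = np.asarray(self.zeta, float).reshape(G, 2)
        self.delta = np.asarray(self.delta, float).ravel()
        if G < 1:
            raise ValidationError("n_classes must be >= 1")
        if G > 1 and self.xi.shape[0] != G - 1:
            raise ValidationError(f"xi must have {G - 1} rows, got {self.xi.shape[0]}")
        if self.beta.shape != (G, 3):
            raise ValidationError(f"beta must be ({G}, 3)")
        if self.sigma <= 0 or np.any(self.zeta <= 0):
            raise ValidationError("sigma and all Weibull parameters must be > 0")
        w = np.linalg.eigvalsh(0.5 * (self.B + self.B.T))
        if w.min() < -1e-10:
            raise ValidationError("random-effect covariance B must be PSD")

    def copy(self) -> "JointModelParams":
        return JointModelParams(
            n_classes=self.n_classes,
            xi=self.xi.copy(),
            beta=self.beta.copy(),
            B=self.B.copy(),
            sigma=self.sigma,
            link=self.link,
            zeta=self.zeta.copy(),
            delta=self.delta.copy(),
        )


@dataclass
class FitResult:
    """A fitted joint latent class model."""

    params: JointModelParams
    loglik: float
    vcov: Optional[np.ndarray]
    n_params: int
    criteria: dict[str, float]
    posterior: np.ndarray  # (n_subjects, G), rows sum to 1
    modal_class: np.ndarray  # (n_subjects,), 0-based
    convergence: dict[str, Any]
    meta: dict[str, Any] = field(default_factory=dict)


def _array_to_json(a: Optional[np.ndarray]) -> Any:
    return None if a is None else np.asarray(a).tolist()


def serialize_model(fit: FitResult) -> dict[str, Any]:
    """Serialize a FitResult into a versioned JSON-compatible document."""
    p = fit.params
    link = p.link
    return {
        "schema_version": SCHEMA_VERSION,
        "params": {
            "n_classes": p.n_classes,
            "xi": _array_to_json(p.xi),
            "beta": _array_to_json(p.beta),
            "B": _array_to_json(p.B),
            "sigma": p.sigma,
            "link": {
                "family": link.family,
                "nodes": _array_to_json(link.nodes),
                "eta": _array_to_json(link.eta),
                "y_range": list(link.y_range),
            },
            "zeta": _array_to_json(p.zeta),
            "delta": _array_to_json(p.delta),
        },
        "loglik": fit.loglik,
        "vcov": _array_to_json(fit.vcov),
        "n_params": fit.n_params,
        "criteria": dict(fit.criteria),
        "posterior": _array_to_json(fit.posterior),
        "modal_class": _array_to_json(fit.modal_class),
        "convergence": dict(fit.convergence),
        "meta": dict(fit.meta),
    }


def deserialize_model(document: dict[str, Any]) -> FitResult:
    """Inverse of :func:`serialize_model`; rejects unknown schema versions."""
    if not isinstance(document, dict) or "schema_version" not in document:
        raise SchemaError("not a serialized model document")
    if document["schema_version"] != SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported schema version {document['schema_version']!r}; "
            f"expected {SCHEMA_VERSION}"
        )
    try:
        pd_ = document["params"]
        ld = pd_["link"]
        link = LinkSpec(
            family=ld["family"],
            nodes=None if ld["nodes"] is None else np.asarray(ld["nodes"], float),
            eta=np.asarray(ld["eta"], float),
            y_range=tuple(ld["y_range"]),
        )
        params = JointModelParams(
            n_classes=int(pd_["n_classes"]),
            xi=np.asarray(pd_["xi"], float) if pd_["xi"] else np.zeros((0, 1)),
            beta=np.asarray(pd_["beta"], float),
            B=np.asarray(pd_["B"], float),
            sigma=float(pd_["sigma"]),
            link=link,
            zeta=np.asarray(pd_["zeta"], float),
            delta=np.asarray(pd_["delta"], float),
        )
        vcov = document["vcov"]
        return FitResult(
            params=params,
            loglik=float(document["loglik"]),
            vcov=None if vcov is None else np.asarray(vcov, float),
            n_params=int(document["n_params"]),
            criteria={k: float(v) for k, v in document["criteria"].items()},
            posterior=np.asarray(document["posterior"], float),
            modal_class=np.asarray(document["modal_class"], int),
            convergence=dict(document["convergence"]),
            meta=dict(document.get("meta", {})),
        )
    except (KeyError, TypeError) as exc:  # truncated / malformed documents
        raise SchemaError(f"malformed model document: {exc}") from exc


def save_model(fit: FitResult, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(serialize_model(fit), fh)


def load_model(path: str) -> FitResult:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"unreadable model document {path}: {exc}") from exc
    return deserialize_model(doc)
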