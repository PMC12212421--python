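"""Synthetic head-and-neck CT phantom cohorts with time-to-event endpoints.

Each patient is a 3D Hounsfield-unit voxel grid containing a soft-tissue body
ellipsoid, a disconnected high-density couch slab, and an ellipsoidal primary
gross tumor volume (GTVp) whose size and intensity heterogeneity carry a latent
prognostic signal.  Event times for overall survival (OS), locoregional control
(LRC) and freedom from distant metastasis (FFDM) follow an exponential
proportional-hazards model on that latent risk, with independent exponential
censoring.  Clinical covariates (age, sex, T/N stage, HPV status, chemotherapy)
are drawn correlated with the latent risk so that clinical baseline models have
a recoverable signal, and values are deleted completely at random to exercise
imputation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

ENDPOINTS = ("OS", "LRC", "FFDM")
HPV_LEVELS = ("positive", "negative", "unknown")

#: marginal cumulative probabilities used for the ordinal N-stage draw
#: (approximately N0 42%, N1 8%, N2 45%, N3 5%)
_N_STAGE_CUM = (0.42, 0.50, 0.95)
#: marginal cumulative probabilities for T stage (T1 20%, T2 32%, T3 29%, T4 19%)
_T_STAGE_CUM = (0.20, 0.52, 0.81)
#: centering constant for the N-stage contribution to the log-hazard
_N_STAGE_MEAN = 1.2

_BODY_HU = 40.0
_TUMOR_HU = 60.0
_BED_HU = 250.0
_AIR_HU = -1000.0


class CohortSizingError(ValueError):
    """Grid too small to contain the tumor plus margin."""


class CohortFormatError(ValueError):
    """On-disk cohort violates the format contract."""


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults define the standard study conditions."""

    n_patients: int = 100
    seed: int = 0
    grid_shape: tuple[int, int, int] = (96, 96, 40)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 3.0)
    tumor_radius_range_mm: tuple[float, float] = (8.0, 22.0)
    risk_coefficients: dict = field(
        default_factory=lambda: {"volume": 0.8, "texture": 0.8, "n_stage": 0.25}
    )
    baseline_hazard_per_month: float = 0.009
    censoring_rate_per_month: float = 0.004
    horizon_months: float = 24.0
    persistence_prob: float = 0.05
    missing_clinical_prob: float = 0.05

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape entries must be positive")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm entries must be positive")
        lo, hi = self.tumor_radius_range_mm
        if not (0 < lo <= hi):
            raise ValueError("tumor_radius_range_mm must be a positive interval")
        if self.baseline_hazard_per_month <= 0:
            raise ValueError("baseline_hazard_per_month must be > 0")
        if self.censoring_rate_per_month <= 0:
            raise ValueError("censoring_rate_per_month must be > 0")
        if self.horizon_months <= 0:
            raise ValueError("horizon_months must be > 0")
        for name in ("persistence_prob", "missing_clinical_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        return json.dumps(d, default=list)

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        d = json.loads(text)
        for key in ("grid_shape", "spacing_mm", "tumor_radius_range_mm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(eq=False)
class PatientRecord:
    patient_id: str
    ct: np.ndarray  # float32 HU
    gtvp_mask: np.ndarray  # uint8 {0,1}
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    clinical: dict  # age, sex, t_stage, n_stage, hpv, chemo (NaN = missing)
    endpoints: dict  # name -> (time_months, event)
    persistent_disease: int
    latent_risk: float

    def __post_init__(self) -> None:
        if self.ct.shape != self.gtvp_mask.shape:
            raise ValueError("ct and gtvp_mask must share shape")
        if not self.gtvp_mask.any():
            raise ValueError("gtvp_mask must be nonempty")
        for name, (t, _e) in self.endpoints.items():
            if t < 0:
                raise ValueError(f"negative event time for endpoint {name}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PatientRecord):
            return NotImplemented
        if self.patient_id != other.patient_id:
            return False
        if not np.array_equal(self.ct, other.ct):
            return False
        if not np.array_equal(self.gtvp_mask, other.gtvp_mask):
            return False
        if not np.allclose(self.spacing, other.spacing):
            return False
        for k in ("age", "sex", "t_stage", "n_stage", "hpv", "chemo"):
            a, b = self.clinical.get(k), other.clinical.get(k)
            if isinstance(a, float) and isinstance(b, float):
                if not (a == b or (math.isnan(a) and math.isnan(b))):
                    return False
            elif a != b:
                return False
        if set(self.endpoints) != set(other.endpoints):
            return False
        for k, (t, e) in self.endpoints.items():
            t2, e2 = other.endpoints[k]
            if not (math.isclose(t, t2, rel_tol=0, abs_tol=1e-9) and e == e2):
                return False
        return (
            self.persistent_disease == other.persistent_disease
            and math.isclose(self.latent_risk, other.latent_risk, abs_tol=1e-9)
        )


@dataclass(frozen=True)
class EndpointLabel:
    patient_id: str
    endpoint: str
    label: str  # positive | negative | excluded
    exclusion_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.label == "excluded" and not self.exclusion_reason:
            raise ValueError("excluded labels require a nonempty reason")


def _ordinal_draw(location: float, cum_probs: Sequence[float], rng: np.random.Generator) -> int:
    """Cumulative-logit ordinal draw: higher location shifts mass upward."""
    u = location + rng.logistic()
    cuts = [math.log(q / (1 - q)) for q in cum_probs]
    return int(sum(u > c for c in cuts))


def _ellipsoid_mask(shape, spacing, center_mm, radii_mm) -> np.ndarray:
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    acc = np.zeros(shape, dtype=float)
    for g, c, r in zip(grids, center_mm, radii_mm):
        acc += ((g - c) / r) ** 2
    return acc <= 1.0


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Draw a fully synthetic cohort; bit-deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.grid_shape)
    spacing = tuple(config.spacing_mm)
    extent_mm = np.array(shape) * np.array(spacing)
    r_lo, r_hi = config.tumor_radius_range_mm
    # tumor (with 15% per-axis jitter) plus a margin must fit inside the grid
    if any(2 * r_hi * 1.15 + 16.0 > e for e in extent_mm):
        raise CohortSizingError(
            f"grid extent {tuple(extent_mm)} mm too small for tumors up to "
            f"{r_hi} mm radius"
        )

    n = config.n_patients
    radii = rng.uniform(r_lo, r_hi, size=n)
    heterogeneity = rng.uniform(5.0, 30.0, size=n)
    axis_jitter = rng.uniform(0.85, 1.15, size=(n, 3))
    center_jitter = rng.uniform(-6.0, 6.0, size=(n, 3))

    # latent risk from standardized log-volume and heterogeneity
    log_vol = 3 * np.log(radii * axis_jitter.prod(axis=1) ** (1 / 3))
    vz = (log_vol - log_vol.mean()) / (log_vol.std() + 1e-12)
    tz = (heterogeneity - heterogeneity.mean()) / (heterogeneity.std() + 1e-12)
    c_vol = float(config.risk_coefficients.get("volume", 0.0))
    c_tex = float(config.risk_coefficients.get("texture", 0.0))
    c_n = float(config.risk_coefficients.get("n_stage", 0.0))
    risk0 = c_vol * vz + c_tex * tz

    records: list[PatientRecord] = []
    body_center = extent_mm / 2.0
    body_radii = np.array(
        [0.38 * extent_mm[0], 0.30 * extent_mm[1], 0.55 * extent_mm[2]]
    )
    for i in range(n):
        ct = rng.normal(_AIR_HU, 8.0, size=shape).astype(np.float32)
        body = _ellipsoid_mask(shape, spacing, body_center, body_radii)
        ct[body] = rng.normal(_BODY_HU, 6.0, size=int(body.sum())).astype(np.float32)

        # couch: thin slab along the posterior (high-y) edge, disconnected from body
        bed = np.zeros(shape, dtype=bool)
        bed[:, -3:, :] = True
        ct[bed] = _BED_HU

        tumor_radii = radii[i] * axis_jitter[i]
        tumor_center = body_center + center_jitter[i]
        tumor = _ellipsoid_mask(shape, spacing, tumor_center, tumor_radii)
        if not tumor.any():
            raise CohortSizingError("tumor fell outside the voxel grid")
        ct[tumor] = (
            _TUMOR_HU + rng.normal(0.0, heterogeneity[i], size=int(tumor.sum()))
        ).astype(np.float32)

        n_stage = _ordinal_draw(risk0[i], _N_STAGE_CUM, rng)
        latent = float(risk0[i] + c_n * (n_stage - _N_STAGE_MEAN))

        hazard = config.baseline_hazard_per_month * math.exp(latent)
        endpoints = {}
        for name in ENDPOINTS:
            t_event = rng.exponential(1.0 / hazard)
            t_cens = rng.exponential(1.0 / config.censoring_rate_per_month)
            endpoints[name] = (float(min(t_event, t_cens)), int(t_event <= t_cens))
        persistent = int(rng.random() < config.persistence_prob)

        t_stage = 1 + _ordinal_draw(1.2 * vz[i], _T_STAGE_CUM, rng)
        age = float(np.clip(63.0 + 8.5 * rng.standard_normal() + 1.5 * latent, 25, 95))
        sex = int(rng.random() < 0.82)  # 1 = male
        if rng.random() < 0.47:
            p_pos = 1.0 / (1.0 + math.exp(-(0.66 - 1.0 * risk0[i])))
            hpv = "positive" if rng.random() < p_pos else "negative"
        else:
            hpv = "unknown"
        chemo = int(rng.random() < float(np.clip(0.65 + 0.08 * risk0[i], 0.05, 0.95)))

        clinical = {
            "age": age,
            "sex": float(sex),
            "t_stage": float(t_stage),
            "n_stage": float(n_stage),
            "hpv": hpv,
            "chemo": float(chemo),
        }
        for key in list(clinical):
            if rng.random() < config.missing_clinical_prob:
                clinical[key] = float("nan") if key != "hpv" else "unknown"

        records.append(
            PatientRecord(
                patient_id=f"P{i:04d}",
                ct=ct,
                gtvp_mask=tumor.astype(np.uint8),
                spacing=spacing,
                origin=(0.0, 0.0, 0.0),
                clinical=clinical,
                endpoints=endpoints,
                persistent_disease=persistent,
                latent_risk=latent,
            )
        )
    return records


def dichotomize_endpoint(
    time_months: float,
    event: int,
    persistent: int,
    endpoint: str,
    horizon: float = 24.0,
    patient_id: str = "",
) -> EndpointLabel:
    """Two-year dichotomization with loss-to-follow-up and persistence exclusions.

    Rules, in order of precedence: persistent disease excludes from LRC; an
    event recorded at time zero is ambiguous and excluded; an event at or
    before the horizon is positive; event-free follow-up reaching the horizon
    is negative; event-free follow-up ending earlier is lost to follow-up.
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    if time_months < 0:
        raise ValueError("time_months must be nonnegative")
    if persistent and endpoint == "LRC":
        return EndpointLabel(patient_id, endpoint, "excluded", "persistent disease")
    if event:
        if time_months == 0:
            return EndpointLabel(patient_id, endpoint, "excluded", "ambiguous")
        if time_months <= horizon:
            return EndpointLabel(patient_id, endpoint, "positive")
        return EndpointLabel(patient_id, endpoint, "negative")
    if time_months >= horizon:
        return EndpointLabel(patient_id, endpoint, "negative")
    return EndpointLabel(patient_id, endpoint, "excluded", "lost to follow-up")


def label_cohort(
    records: Sequence[PatientRecord], endpoint: str, horizon: float = 24.0
) -> list[EndpointLabel]:
    return [
        dichotomize_endpoint(
            *r.endpoints[endpoint],
            persistent=r.persistent_disease,
            endpoint=endpoint,
            horizon=horizon,
            patient_id=r.patient_id,
        )
        for r in records
    ]


# ---------------------------------------------------------------------------
# On-disk round trip: NIfTI volumes + CSV tables + JSON manifest
# ---------------------------------------------------------------------------


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def write_cohort(records: Sequence[PatientRecord], directory: str | Path) -> dict:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    clin_rows, ep_rows = [], []
    truth = {}
    for r in records:
        aff = _affine(r.spacing, r.origin)
        nib.save(nib.Nifti1Image(r.ct, aff), directory / f"{r.patient_id}_ct.nii.gz")
        nib.save(
            nib.Nifti1Image(r.gtvp_mask, aff),
            directory / f"{r.patient_id}_mask.nii.gz",
        )
        clin_rows.append({"patient_id": r.patient_id, **r.clinical})
        for name, (t, e) in r.endpoints.items():
            ep_rows.append(
                {
                    "patient_id": r.patient_id,
                    "endpoint": name,
                    "time_months": t,
                    "event": e,
                    "persistent": r.persistent_disease,
                }
            )
        truth[r.patient_id] = r.latent_risk
    pd.DataFrame(clin_rows).to_csv(directory / "clinical.csv", index=False)
    pd.DataFrame(ep_rows).to_csv(directory / "endpoints.csv", index=False)
    manifest = {
        "patient_ids": [r.patient_id for r in records],
        "latent_risk": truth,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_cohort(directory: str | Path) -> list[PatientRecord]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    clin = pd.read_csv(directory / "clinical.csv").set_index("patient_id")
    eps = pd.read_csv(directory / "endpoints.csv")
    bad_hpv = set(clin["hpv"].dropna()) - set(HPV_LEVELS)
    if bad_hpv:
        raise CohortFormatError(f"unknown HPV category value(s): {sorted(bad_hpv)}")
    records = []
    for pid in manifest["patient_ids"]:
        ct_img = nib.load(directory / f"{pid}_ct.nii.gz")
        mask_img = nib.load(directory / f"{pid}_mask.nii.gz")
        ct = np.asarray(ct_img.dataobj, dtype=np.float32)
        mask = np.asarray(mask_img.dataobj, dtype=np.uint8)
        if ct.shape != mask.shape:
            raise CohortFormatError(
                f"{pid}: CT shape {ct.shape} != mask shape {mask.shape}"
            )
        if not np.allclose(ct_img.affine, mask_img.affine, atol=1e-4):
            raise CohortFormatError(f"{pid}: CT and mask affines differ")
        spacing = tuple(float(s) for s in ct_img.header.get_zooms()[:3])
        origin = tuple(float(x) for x in ct_img.affine[:3, 3])
        row = clin.loc[pid]
        clinical = {
            "age": float(row["age"]),
            "sex": float(row["sex"]),
            "t_stage": float(row["t_stage"]),
            "n_stage": float(row["n_stage"]),
            "hpv": str(row["hpv"]),
            "chemo": float(row["chemo"]),
        }
        sub = eps[eps["patient_id"] == pid]
        endpoints = {
            r["endpoint"]: (float(r["time_months"]), int(r["event"]))
            for _, r in sub.iterrows()
        }
        records.append(
            PatientRecord(
                patient_id=pid,
                ct=ct,
                gtvp_mask=mask,
                spacing=spacing,
                origin=origin,
                clinical=clinical,
                endpoints=endpoints,
                persistent_disease=int(sub["persistent"].iloc[0]),
                latent_risk=float(manifest["latent_risk"][pid]),
            )
        )
    return records
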