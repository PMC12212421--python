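"""Clinical baseline, imputation, multimodal fusion and multivariate analysis.

The baseline uses the established prognostic variables for head-and-neck
cancer — T stage, N stage, HPV status — plus age, sex and chemotherapy flag,
in a class-weight-balanced logistic regression.  Missing values are imputed
with training-set means (numeric) or modes (categorical), frozen for test
cohorts.  HPV is dummy-coded against a "negative" reference; stages enter as
ordinal integers by default, with dummy coding available.  The multimodal
model appends the MIL score as one numeric covariate; the multivariate
log-odds-ratio report comes from an unpenalized fit with Wald intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression

NUMERIC_COLUMNS = ("age",)
CATEGORICAL_COLUMNS = ("sex", "t_stage", "n_stage", "hpv", "chemo")
RAW_COLUMNS = NUMERIC_COLUMNS + CATEGORICAL_COLUMNS


@dataclass
class CoefficientReport:
    table: pd.DataFrame  # index: variable; columns: lor, ci_low, ci_high, p
    separation_flag: bool = False
    collinearity_flag: bool = False
    converged: bool = True

    def __post_init__(self) -> None:
        ok = self.table.dropna()
        if not (
            (ok["ci_low"] <= ok["lor"] + 1e-9) & (ok["lor"] <= ok["ci_high"] + 1e-9)
        ).all():
            raise ValueError("confidence interval must contain the point estimate")


class ClinicalPreprocessor:
    """Mean/mode imputation with frozen training parameters, then encoding."""

    def __init__(self, stage_coding: str = "ordinal"):
        if stage_coding not in ("ordinal", "dummy"):
            raise ValueError("stage_coding must be 'ordinal' or 'dummy'")
        self.stage_coding = stage_coding
        self.impute_values: dict = {}

    def fit(self, raw: pd.DataFrame) -> "ClinicalPreprocessor":
        for col in RAW_COLUMNS:
            series = raw[col]
            if col == "hpv":
                known = series.dropna()
            else:
                known = pd.to_numeric(series, errors="coerce").dropna()
            if known.empty:
                raise ValueError(f"column {col!r} is fully missing; cannot impute")
            if col in NUMERIC_COLUMNS:
                self.impute_values[col] = float(known.mean())
            else:
                # mode; deterministic tie-break on sorted values
                self.impute_values[col] = sorted(known.mode().tolist())[0]
        return self

    def impute(self, raw: pd.DataFrame) -> pd.DataFrame:
        if not self.impute_values:
            raise RuntimeError("preprocessor not fitted")
        out = raw.copy()
        for col in RAW_COLUMNS:
            if col == "hpv":
                out[col] = out[col].fillna(self.impute_values[col])
            else:
                out[col] = pd.to_numeric(out[col], errors="coerce").fillna(
                    self.impute_values[col]
                )
        return out

    def encode(self, imputed: pd.DataFrame) -> pd.DataFrame:
        """Design matrix: numeric age, binary sex/chemo, staged T/N, HPV dummies."""
        X = pd.DataFrame(index=imputed.index)
        X["age"] = imputed["age"].astype(float)
        X["sex"] = imputed["sex"].astype(float)
        X["chemo"] = imputed["chemo"].astype(float)
        if self.stage_coding == "ordinal":
            X["t_stage"] = imputed["t_stage"].astype(float)
            X["n_stage"] = imputed["n_stage"].astype(float)
        else:
            for col, levels in (("t_stage", (2, 3, 4)), ("n_stage", (1, 2, 3))):
                vals = imputed[col].astype(float)
                for lv in levels:
                    X[f"{col}_{lv}"] = (vals == lv).astype(float)
        # HPV reference level = negative
        X["hpv_positive"] = (imputed["hpv"] == "positive").astype(float)
        X["hpv_unknown"] = (imputed["hpv"] == "unknown").astype(float)
        return X

    def transform(self, raw: pd.DataFrame) -> pd.DataFrame:
        return self.encode(self.impute(raw))


def clinical_table(records: Sequence) -> pd.DataFrame:
    """Raw clinical DataFrame (index patient_id) from PatientRecord objects."""
    rows = {r.patient_id: dict(r.clinical) for r in records}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "patient_id"
    return df[list(RAW_COLUMNS)]


def impute_clinical(
    raw: pd.DataFrame, preprocessor: Optional[ClinicalPreprocessor] = None,
    stage_coding: str = "ordinal",
) -> tuple[pd.DataFrame, ClinicalPreprocessor]:
    """Imputed + encoded design matrix; fits the preprocessor when not given."""
    if preprocessor is None:
        preprocessor = ClinicalPreprocessor(stage_coding=stage_coding).fit(raw)
    return preprocessor.transform(raw), preprocessor


@dataclass
class ClinicalModel:
    """Balanced-class-weight logistic model over a fixed column set."""

    columns: list
    clf: LogisticRegression = field(default_factory=lambda: LogisticRegression(
        class_weight="balanced", max_iter=5000))

    def fit(self, X: pd.DataFrame, labels: Sequence[int]) -> "ClinicalModel":
        y = np.asarray(labels, dtype=int)
        if np.unique(y).size < 2:
            raise ValueError("labels contain a single class")
        self.clf.fit(X[self.columns].to_numpy(dtype=float), y)
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self.clf.predict_proba(X[self.columns].to_numpy(dtype=float))[:, 1]


def fit_clinical_baseline(matrix: pd.DataFrame, labels: Sequence[int]) -> ClinicalModel:
    return ClinicalModel(columns=list(matrix.columns)).fit(matrix, labels)


def _fuse(matrix: pd.DataFrame, mil_scores: pd.Series) -> pd.DataFrame:
    if not matrix.index.equals(mil_scores.index):
        if set(matrix.index) != set(mil_scores.index):
            raise ValueError("clinical matrix and MIL scores have misaligned patients")
        mil_scores = mil_scores.reindex(matrix.index)
    fused = matrix.copy()
    fused["mil_score"] = mil_scores.astype(float)
    return fused


def fit_multimodal(
    matrix: pd.DataFrame, mil_scores: pd.Series, labels: Sequence[int]
) -> ClinicalModel:
    """Balanced logistic model on clinical covariates plus the MIL score."""
    fused = _fuse(matrix, mil_scores)
    return ClinicalModel(columns=list(fused.columns)).fit(fused, labels)


def predict_multimodal(
    model: ClinicalModel, matrix: pd.DataFrame, mil_scores: pd.Series
) -> np.ndarray:
    return model.predict_proba(_fuse(matrix, mil_scores))


def multivariate_lor(
    matrix: pd.DataFrame,
    mil_scores: Optional[pd.Series],
    labels: Sequence[int],
) -> CoefficientReport:
    """Unpenalized multivariate logistic fit with Wald CIs per coefficient.

    Collinear designs and (quasi-)perfect separation are flagged rather than
    reported as silently diverged estimates.
    """
    X = _fuse(matrix, mil_scores) if mil_scores is not None else matrix.copy()
    y = np.asarray(labels, dtype=int)
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    collinear = np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]
    separation = False
    converged = True
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", True))
        params, bse, pvals = res.params, res.bse, res.pvalues
    except Exception:
        separation, converged = True, False
        params = pd.Series(np.nan, index=Xc.columns)
        bse = pd.Series(np.nan, index=Xc.columns)
        pvals = pd.Series(np.nan, index=Xc.columns)
    if np.abs(params.to_numpy()).max() > 50 or not converged:
        separation = True
    table = pd.DataFrame(
        {
            "lor": params,
            "ci_low": params - 1.96 * bse,
            "ci_high": params + 1.96 * bse,
            "p": pvals,
        }
    )
    return CoefficientReport(
        table=table,
        separation_flag=separation,
        collinearity_flag=bool(collinear),
        converged=converged,
    )


SUBGROUP_RULES = ("all", "non_hpv_positive", "contrast", "non_contrast")


def subgroup_filter(cohort: Sequence, rule: str) -> list:
    """Cohort subsets; non_hpv_positive keeps HPV-negative and HPV-unknown.

    The synthetic phantoms carry no contrast-enhancement flag, so the contrast
    rules select on a 'contrast' key in the clinical map when present and
    otherwise keep nothing / everything respectively.
    """
    if rule not in SUBGROUP_RULES:
        raise ValueError(f"unknown subgroup rule {rule!r}")
    if rule == "all":
        return list(cohort)
    out = []
    for r in cohort:
        clin = r.clinical if hasattr(r, "clinical") else r
        if rule == "non_hpv_positive":
            if clin.get("hpv") != "positive":
                out.append(r)
        elif rule == "contrast":
            if clin.get("contrast", 0):
                out.append(r)
        elif rule == "non_contrast":
            if not clin.get("contrast", 0):
                out.append(r)
    if not out:
        import warnings

        warnings.warn(f"subgroup {rule!r} selected no patients", stacklevel=2)
    return out
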