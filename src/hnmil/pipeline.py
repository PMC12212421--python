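"""End-to-end experiment orchestration.

simulate -> preprocess -> extract -> train -> predict -> evaluate, on a
training cohort and an independently seeded test cohort, with one global seed
fanned out deterministically to per-stage seeds so stages can be re-run in
isolation.  The report collects, per endpoint and model, test AUROC with
bootstrap CI, training-median stratification of the full time-to-event data,
pairwise permutation tests with Benjamini-Hochberg adjustment, and the
score-to-clinical correlation table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import clinical as clin
from . import features as feat
from . import mil as milmod
from . import preprocess as prep
from . import radiomics as rad
from . import stats as st
from . import synthetic as syn

log = logging.getLogger("hnmil")

MODES = ("2d_axial", "multiview", "3d")
_MODE_VIEWS = {"2d_axial": ("axial",), "multiview": prep.VIEWS}


@dataclass(frozen=True)
class ExperimentConfig:
    cohort: syn.CohortConfig = field(default_factory=syn.CohortConfig)
    n_test: int = 60
    mode: str = "2d_axial"
    extractor_dim: int = 128
    mil_epochs: int = 10
    mil_model_dim: int = 64
    mil_layers: int = 2
    mil_heads: int = 4
    mil_folds: int = 5
    mil_batch_size: int = 8
    n_subvolumes: int = 100
    endpoints: tuple = ("OS",)
    with_radiomics: bool = True
    with_clinical: bool = True
    with_multimodal: bool = True
    n_boot: int = 1000
    n_perm: int = 1000
    seed: int = 1337

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not self.endpoints:
            raise ValueError("at least one endpoint required")
        for e in self.endpoints:
            if e not in syn.ENDPOINTS:
                raise ValueError(f"unknown endpoint {e!r}")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _extractor_for(config: ExperimentConfig) -> feat.ToyExtractor:
    kind = "subvolume3d" if config.mode == "3d" else "patch2d"
    spec = feat.ExtractorSpec(
        name="toy", embedding_dim=config.extractor_dim, input_kind=kind,
        seed=stage_seed(config.seed, "extractor"),
    )
    return feat.toy_extractor(spec)


def build_bags(
    records: Sequence[syn.PatientRecord],
    config: ExperimentConfig,
    extractor,
    rng: np.random.Generator,
) -> dict:
    """patient_id -> InstanceBag for the configured instance mode."""
    bags = {}
    for r in records:
        if config.mode == "3d":
            instances = prep.preprocess_for_3d(
                r.ct, r.gtvp_mask, r.spacing, rng, n=config.n_subvolumes,
                patient_id=r.patient_id,
            )
        else:
            instances = prep.preprocess_for_2d(
                r.ct, r.gtvp_mask, r.spacing, views=_MODE_VIEWS[config.mode],
                patient_id=r.patient_id,
            )
        bags[r.patient_id] = feat.embed_bag(
            instances, extractor, rng, patient_id=r.patient_id
        )
    return bags


def _included(labels: Sequence[syn.EndpointLabel]) -> tuple[list, np.ndarray]:
    ids = [l.patient_id for l in labels if l.label != "excluded"]
    y = np.array([1 if l.label == "positive" else 0
                  for l in labels if l.label != "excluded"], dtype=int)
    return ids, y


def _auroc_block(scores, y, rng, n_boot) -> dict:
    res = st.bootstrap_auroc_ci(scores, y, n_boot=n_boot, rng=rng)
    return {"auroc": res.auroc, "ci_low": res.ci_low, "ci_high": res.ci_high,
            "n_boot": res.n_boot, "n": int(len(y))}


def _strat_block(train_scores, test_scores, times, events) -> dict:
    s = st.stratify_by_median(train_scores, test_scores, times, events)
    return {
        "cutoff": s.cutoff,
        "hr": s.hr,
        "hr_ci": list(s.hr_ci) if s.hr_ci else None,
        "logrank_p": s.logrank_p,
        "degenerate": bool(s.degenerate_flag),
    }


def run_experiment(config: ExperimentConfig, out_dir: Optional[str | Path] = None) -> dict:
    """Execute every configured stage; fully reproducible from config + seed."""
    train_cfg = dataclasses.replace(config.cohort, seed=stage_seed(config.seed, "train_cohort"))
    test_cfg = dataclasses.replace(
        config.cohort, n_patients=config.n_test,
        seed=stage_seed(config.seed, "test_cohort"),
    )
    log.info("simulating cohorts: train n=%d, test n=%d", train_cfg.n_patients, config.n_test)
    train_records = syn.generate_cohort(train_cfg)
    test_records = syn.generate_cohort(test_cfg)
    for r in test_records:  # keep ids disjoint from the training cohort
        r.patient_id = "T" + r.patient_id

    extractor = _extractor_for(config)
    rng_feat = np.random.default_rng(stage_seed(config.seed, "features"))
    log.info("preprocessing and embedding (%s)", config.mode)
    train_bags = build_bags(train_records, config, extractor, rng_feat)
    test_bags = build_bags(test_records, config, extractor, rng_feat)

    rad_table_train = rad.extract_feature_table(train_records) if config.with_radiomics else None
    rad_table_test = rad.extract_feature_table(test_records) if config.with_radiomics else None
    clin_train_raw = clin.clinical_table(train_records)
    clin_test_raw = clin.clinical_table(test_records)

    report = {
        "provenance": {
            "seed": config.seed,
            "mode": config.mode,
            "extractor_dim": config.extractor_dim,
            "n_train": len(train_records),
            "n_test": len(test_records),
            "stage_seeds": {s: stage_seed(config.seed, s)
                            for s in ("train_cohort", "test_cohort", "features",
                                      "mil", "stats")},
        },
        "endpoints": {},
    }

    for endpoint in config.endpoints:
        tr_ids, y_tr = _included(syn.label_cohort(train_records, endpoint,
                                                  config.cohort.horizon_months))
        te_ids, y_te = _included(syn.label_cohort(test_records, endpoint,
                                                  config.cohort.horizon_months))
        log.info("endpoint %s: train %d (pos %d), test %d (pos %d)",
                 endpoint, len(tr_ids), y_tr.sum(), len(te_ids), y_te.sum())
        ep_report = {"models": {}, "comparisons": {}}
        rng_stats = np.random.default_rng(stage_seed(config.seed, f"stats_{endpoint}"))

        mil_cfg = milmod.MILConfig(
            embed_dim_in=config.extractor_dim, model_dim=config.mil_model_dim,
            n_layers=config.mil_layers, n_heads=config.mil_heads,
            batch_size=config.mil_batch_size,
            epochs=config.mil_epochs, patience=min(config.mil_epochs, 15),
            n_folds=config.mil_folds, seed=stage_seed(config.seed, f"mil_{endpoint}"),
        )
        fold_models = milmod.train_mil_cv([train_bags[i] for i in tr_ids], y_tr, mil_cfg)
        deployed = milmod.select_deployment_model(fold_models)
        # out-of-fold training scores: unbiased inputs for the median cutoff,
        # the multivariate LOR analysis and the fusion fit
        mil_train = milmod.cross_val_scores([train_bags[i] for i in tr_ids],
                                            fold_models)
        mil_test = np.array([milmod.mil_forward(test_bags[i], deployed).score
                             for i in te_ids])
        # survival arrays aligned to te_ids
        by_id = {r.patient_id: r for r in test_records}
        times = np.array([by_id[i].endpoints[endpoint][0] for i in te_ids])
        events = np.array([by_id[i].endpoints[endpoint][1] for i in te_ids])

        model_scores = {"mil": mil_test}
        ep_report["models"]["mil"] = {
            "holdout_aurocs": [m.holdout_auroc for m in fold_models],
            "deployed_fold": deployed.fold_id,
            "test": _auroc_block(mil_test, y_te, rng_stats, config.n_boot),
            "stratification": _strat_block(mil_train, mil_test, times, events),
        }

        if config.with_radiomics:
            trace = rad.select_features(rad_table_train.loc[tr_ids], y_tr,
                                        seed=stage_seed(config.seed, "radiomics"))
            rmodel = rad.fit_radiomics_classifier(rad_table_train.loc[tr_ids],
                                                  y_tr, trace.selected)
            rad_train = rmodel.predict_proba(rad_table_train.loc[tr_ids])
            rad_test = rmodel.predict_proba(rad_table_test.loc[te_ids])
            model_scores["radiomics"] = rad_test
            ep_report["models"]["radiomics"] = {
                "selected_features": trace.selected,
                "k_selected": trace.k_selected,
                "test": _auroc_block(rad_test, y_te, rng_stats, config.n_boot),
                "stratification": _strat_block(rad_train, rad_test, times, events),
            }

        if config.with_clinical:
            X_tr, pre = clin.impute_clinical(clin_train_raw.loc[tr_ids])
            X_te = pre.transform(clin_test_raw.loc[te_ids])
            cmodel = clin.fit_clinical_baseline(X_tr, y_tr)
            clin_train_scores = cmodel.predict_proba(X_tr)
            clin_test_scores = cmodel.predict_proba(X_te)
            model_scores["clinical"] = clin_test_scores
            ep_report["models"]["clinical"] = {
                "test": _auroc_block(clin_test_scores, y_te, rng_stats, config.n_boot),
                "stratification": _strat_block(clin_train_scores, clin_test_scores,
                                               times, events),
            }
            lor = clin.multivariate_lor(X_tr, pd.Series(mil_train, index=X_tr.index),
                                        y_tr)
            ep_report["mil_lor"] = {
                "lor": float(lor.table.loc["mil_score", "lor"]),
                "ci_low": float(lor.table.loc["mil_score", "ci_low"]),
                "ci_high": float(lor.table.loc["mil_score", "ci_high"]),
                "p": float(lor.table.loc["mil_score", "p"]),
                "separation_flag": lor.separation_flag,
                "collinearity_flag": lor.collinearity_flag,
            }
            corr = st.correlate_scores_clinical(mil_test, X_te)
            ep_report["correlations"] = corr.to_dict(orient="records")

            if config.with_multimodal:
                mmodel = clin.fit_multimodal(X_tr, pd.Series(mil_train, index=X_tr.index),
                                             y_tr)
                mm_train = clin.predict_multimodal(
                    mmodel, X_tr, pd.Series(mil_train, index=X_tr.index))
                mm_test = clin.predict_multimodal(
                    mmodel, X_te, pd.Series(mil_test, index=X_te.index))
                model_scores["multimodal"] = mm_test
                ep_report["models"]["multimodal"] = {
                    "test": _auroc_block(mm_test, y_te, rng_stats, config.n_boot),
                    "stratification": _strat_block(mm_train, mm_test, times, events),
                }

        names = sorted(model_scores)
        raw_ps, pairs = [], []
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                raw_ps.append(st.permutation_auroc_test(
                    model_scores[a], model_scores[b], y_te, n=config.n_perm,
                    rng=rng_stats))
                pairs.append((a, b))
        adj = st.bh_adjust(raw_ps) if raw_ps else []
        ep_report["comparisons"] = {
            f"{a}_vs_{b}": {"p_raw": float(p), "p_adj": float(q)}
            for (a, b), p, q in zip(pairs, raw_ps, adj)
        }
        report["endpoints"][endpoint] = ep_report

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=1))
    return report


def compare_models(
    report: dict,
    comparisons: Sequence[tuple[str, str]],
    endpoint: str,
) -> pd.DataFrame:
    """BH-adjusted permutation p-values for a family of stored comparisons."""
    ep = report["endpoints"][endpoint]
    rows = []
    for a, b in comparisons:
        for key in (f"{a}_vs_{b}", f"{b}_vs_{a}"):
            if key in ep["comparisons"]:
                rows.append({"pair": f"{a}_vs_{b}",
                             "p_raw": ep["comparisons"][key]["p_raw"]})
                break
        else:
            raise KeyError(f"comparison {a} vs {b} not in report")
    df = pd.DataFrame(rows)
    df["p_adj"] = st.bh_adjust(df["p_raw"].to_numpy())
    return df
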