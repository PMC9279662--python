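"""End-to-end pipeline: simulate/load -> preprocess -> extract ->
split -> select -> score -> fit the four risk models -> evaluate.

All selection, signature fitting and cutoff choices use the primary cohort
only; the test cohort is scored once.  Every stage is deterministic given
(config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import models as riskmodels
from .cohort import CohortConfig, generate_cohort
from .features import FeatureKey, extract_all
from .preprocess import preprocess_study
from .selection import SelectionConfig, lasso_select, spearman_filter
from .signature import SignatureModel, rad_score
from .io import clinical_to_frame

__all__ = ["PipelineConfig", "EvaluationReport", "extract_cohort_features",
           "build_signature", "evaluate_models", "run_pipeline"]

log = logging.getLogger(__name__)

#: Primary-cohort fraction mirroring the 114/165 temporal split of the
#: reference study (applied as an index split on synthetic cohorts).
PRIMARY_FRACTION = 114 / 165


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    g: int = 64
    target_spacing: float = 1.0
    erosion_mm: float = 1.0
    primary_fraction: float = PRIMARY_FRACTION
    n_bootstrap: int = 2000
    hl_groups: int = 10
    seed: int = 0


@dataclass
class EvaluationReport:
    auc: dict  # model -> cohort -> (auc, lo, hi)
    c_index: dict  # cohort -> value (combined nomogram model)
    hosmer_lemeshow: dict  # cohort -> (chi2, p)
    calibration: dict  # cohort -> calibration table (records)
    nomogram: dict
    km: dict  # cohort -> {logrank_p, cutoff, ...}
    signature: dict
    n_primary: int = 0
    n_test: int = 0

    def to_dict(self) -> dict:
        def clean(x):
            if isinstance(x, dict):
                return {str(k): clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [clean(v) for v in x]
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            if isinstance(x, pd.DataFrame):
                return x.to_dict(orient="records")
            return x
        return clean(asdict(self))


def extract_cohort_features(studies, g: int = 64, target_spacing: float = 1.0,
                            erosion_mm: float = 1.0) -> pd.DataFrame:
    """Feature matrix (patients x features) with string-serialized keys."""
    rows, index = [], []
    for study in studies:
        prep = preprocess_study(study, target_spacing=target_spacing,
                                erosion_mm=erosion_mm)
        fv = extract_all(prep, g=g)
        rows.append({str(k): v for k, v in fv.values.items()})
        index.append(study.patient_id)
    return pd.DataFrame(rows, index=index)


def build_signature(features: pd.DataFrame, y: np.ndarray,
                    config: SelectionConfig) -> tuple[SignatureModel, dict]:
    """Three-step selection on the primary cohort -> fitted SignatureModel."""
    retained, drop_log = spearman_filter(features, config.spearman_threshold)
    result = lasso_select(features[retained], y, config)
    model = SignatureModel(
        intercept=result.intercept,
        terms=[(FeatureKey.parse(col), coef)
               for col, coef in result.coefficients.items()],
        note=f"fitted signature; lambda={result.selected_lambda:.5g}",
    )
    detail = {
        "n_input": features.shape[1],
        "n_after_spearman": len(retained),
        "n_selected": len(result.coefficients),
        "selected_lambda": result.selected_lambda,
        "drop_log_size": len(drop_log),
        "lambda_path": result.lambda_path,
        "cv_deviance": result.cv_deviance,
    }
    return model, detail


def score_cohort(features: pd.DataFrame, model: SignatureModel) -> pd.Series:
    values_needed = [str(k) for k, _ in model.terms]
    missing = [c for c in values_needed if c not in features.columns]
    if missing:
        raise KeyError(f"feature matrix missing signature columns: {missing}")
    scores = []
    for _, row in features.iterrows():
        vec = {k: float(row[str(k)]) for k, _ in model.terms}
        scores.append(rad_score(vec, model))
    return pd.Series(scores, index=features.index, name="rad_score")


def evaluate_models(table_primary: pd.DataFrame, table_test: pd.DataFrame,
                    n_bootstrap: int = 2000, hl_groups: int = 10,
                    seed: int = 0) -> EvaluationReport:
    """Fit the four risk models on the primary cohort and evaluate both."""
    fitted: dict[str, riskmodels.RiskModelSpec] = {}
    for name, covs in riskmodels.MODEL_COVARIATES.items():
        spec = riskmodels.RiskModelSpec(name=name, covariates=covs)
        fitted[name] = riskmodels.fit_risk_model(spec, table_primary,
                                                 allow_penalized=True)
    auc: dict = {}
    for name, model in fitted.items():
        auc[name] = {}
        for cohort_name, tab in (("primary", table_primary), ("test", table_test)):
            pred = model.predict(tab)
            auc[name][cohort_name] = riskmodels.roc_auc(
                pred, tab["os_5yr"].astype(int), n_boot=n_bootstrap, seed=seed
            )
    combined = fitted["combined"]
    cindex, hl, calib = {}, {}, {}
    for cohort_name, tab in (("primary", table_primary), ("test", table_test)):
        pred = combined.predict(tab)
        y = tab["os_5yr"].astype(int).to_numpy()
        cindex[cohort_name] = riskmodels.c_index(pred, y)
        chi2, p, curve = riskmodels.hosmer_lemeshow(pred, y, groups=hl_groups)
        hl[cohort_name] = (chi2, p)
        calib[cohort_name] = curve
    nomogram = riskmodels.build_nomogram(combined, table_primary)
    nomogram_out = {
        "predictors": nomogram["predictors"],
        "eta_reference": nomogram["eta_reference"],
        "units_per_point": nomogram["units_per_point"],
    }

    km: dict = {}
    scores_primary = table_primary["rad_score"].to_numpy()
    if np.unique(scores_primary).size < 2:
        km["note"] = "constant radiomics score; stratification not applicable"
    else:
        cutoff = riskmodels.youden_cutoff(scores_primary,
                                          table_primary["os_5yr"].astype(int))
        for cohort_name, tab in (("primary", table_primary), ("test", table_test)):
            try:
                res = riskmodels.km_stratify(
                    tab["rad_score"].to_numpy(),
                    tab["survival_months"].to_numpy(),
                    ~tab["os_5yr"].astype(bool).to_numpy(),
                    cutoff,
                )
                km[cohort_name] = {k: v for k, v in res.items() if k != "curves"}
            except ValueError as exc:
                km[cohort_name] = {"note": str(exc)}
    return EvaluationReport(
        auc=auc, c_index=cindex, hosmer_lemeshow=hl, calibration=calib,
        nomogram=nomogram_out, km=km, signature={},
        n_primary=len(table_primary), n_test=len(table_test),
    )


def run_pipeline(config: PipelineConfig, output_dir: str | Path | None = None
                 ) -> EvaluationReport:
    cohort = generate_cohort(config.cohort)
    studies = [s for s, _ in cohort]
    clinical = clinical_to_frame([r for _, r in cohort])
    features = extract_cohort_features(
        studies, g=config.g, target_spacing=config.target_spacing,
        erosion_mm=config.erosion_mm,
    )
    n = len(cohort)
    n_primary = int(round(config.primary_fraction * n))
    idx_primary = features.index[:n_primary]
    idx_test = features.index[n_primary:]

    y_primary = clinical.loc[idx_primary, "os_5yr"].astype(int).to_numpy()
    sig_model, sel_detail = build_signature(
        features.loc[idx_primary], y_primary, config.selection
    )
    scores = score_cohort(features, sig_model)
    table = clinical.join(scores)
    report = evaluate_models(
        table.loc[idx_primary], table.loc[idx_test],
        n_bootstrap=config.n_bootstrap, hl_groups=config.hl_groups,
        seed=config.seed,
    )
    report.signature = {
        "intercept": sig_model.intercept,
        "terms": [[str(k), c] for k, c in sig_model.terms],
        "n_after_spearman": sel_detail["n_after_spearman"],
        "selected_lambda": sel_detail["selected_lambda"],
    }
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        features.to_csv(out / "features.csv")
        table.to_csv(out / "cohort_table.csv")
        sig_model.to_json(out / "signature.json")
        report_dict = report.to_dict()
        (out / "evaluation.json").write_text(json.dumps(report_dict, indent=2))
        manifest = {
            "config_hash": hashlib.sha256(
                json.dumps(_config_dict(config), sort_keys=True).encode()
            ).hexdigest(),
            "config": _config_dict(config),
            "n_patients": n,
            "n_primary": int(n_primary),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["cohort"]["effect_sizes"] = dict(config.cohort.effect_sizes)
    return d
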