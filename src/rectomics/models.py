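"""Risk models and their evaluation: discrimination, calibration,
nomogram point tables and Kaplan-Meier risk stratification.

Four logistic risk models for the binary 5-year OS endpoint are compared:
``tnm`` (stage only), ``clinical`` (clinical-histological-radiological,
non-radiomics), ``radiomics`` (Rad_score only) and ``combined`` (clinical
covariates plus Rad_score).  Discrimination is AUC with a stratified
bootstrap CI; Harrell's C-index equals AUC for a binary endpoint and is
computed through the same tie-aware rank statistic.  Calibration uses
decile-of-risk Hosmer-Lemeshow; risk groups are split at the Youden-optimal
cutoff frozen on the primary cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from scipy.stats import rankdata

import statsmodels.api as sm

__all__ = [
    "RiskModelSpec",
    "MODEL_COVARIATES",
    "CATEGORICAL_LEVELS",
    "encode_design",
    "fit_risk_model",
    "roc_auc",
    "c_index",
    "hosmer_lemeshow",
    "build_nomogram",
    "youden_cutoff",
    "km_stratify",
    "cohort_compare",
    "fisher_exact_2xk",
    "feature_clinical_heatmap",
]

log = logging.getLogger(__name__)

#: Categorical covariates with fixed level order; the first level is the
#: reference of the one-hot encoding.
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "gender": ("male", "female"),
    "stage": ("IIA", "IIB", "IIIA", "IIIB", "IIIC"),
    "surgery": ("LAR", "APR", "Hartmann", "other"),
    "chemo": ("none", "Folfox", "Xelox"),
    "location": ("low", "mid", "high"),
    "y_n": ("N0", "N1", "N2"),
    "c_t": ("T2", "T3", "T4"),
    "c_n": ("N0", "N1", "N2"),
    "y_t": ("T2", "T3", "T4"),
    "histology": ("I", "II", "III", "IV"),
}

#: Covariate sets of the four risk models.  The clinical set keeps the
#: factors the cohort comparison flags as prognostic (stage, gender, CEA,
#: tumor deposits, nodal ratio and stage) without exhausting the
#: events-per-variable budget of a ~114-patient cohort.
MODEL_COVARIATES: dict[str, tuple[str, ...]] = {
    "tnm": ("stage",),
    "clinical": ("stage", "gender", "cea", "tumor_deposit", "lnr", "y_n"),
    "radiomics": ("rad_score",),
    "combined": ("stage", "gender", "cea", "tumor_deposit", "lnr", "y_n",
                 "rad_score"),
}


@dataclass
class RiskModelSpec:
    name: str
    covariates: tuple[str, ...]
    intercept: float | None = None
    coefficients: dict[str, float] = field(default_factory=dict)
    penalized: bool = False

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        if self.intercept is None:
            raise RuntimeError("model has not been fitted")
        X = encode_design(table, self.covariates)
        eta = self.intercept + sum(
            self.coefficients.get(c, 0.0) * X[c].to_numpy() for c in X.columns
        )
        return 1.0 / (1.0 + np.exp(-eta))


def encode_design(table: pd.DataFrame, covariates: tuple[str, ...]) -> pd.DataFrame:
    """One-hot design matrix with documented reference levels (no intercept)."""
    out = {}
    for cov in covariates:
        if cov in CATEGORICAL_LEVELS:
            levels = CATEGORICAL_LEVELS[cov]
            vals = table[cov].astype(str)
            unknown = set(vals) - set(levels)
            if unknown:
                raise ValueError(f"unknown {cov} levels: {sorted(unknown)}")
            for lv in levels[1:]:
                out[f"{cov}[{lv}]"] = (vals == lv).astype(float).to_numpy()
        elif cov == "tumor_deposit":
            out[cov] = table[cov].astype(float).to_numpy()
        else:
            out[cov] = table[cov].astype(float).to_numpy()
    return pd.DataFrame(out, index=table.index)


def fit_risk_model(spec: RiskModelSpec, table: pd.DataFrame,
                   outcome: str = "os_5yr", allow_penalized: bool = False
                   ) -> RiskModelSpec:
    """Maximum-likelihood logistic fit of one risk model.

    Separation (non-finite or exploding coefficients) raises unless
    ``allow_penalized``, in which case an L2-regularized refit is used and
    flagged on the returned spec.  All-constant dummy columns are dropped.
    """
    y = table[outcome].astype(float).to_numpy()
    if y.min() == y.max():
        raise ValueError("outcome is degenerate (single class)")
    X = encode_design(table, spec.covariates)
    keep = [c for c in X.columns if X[c].std() > 0]
    dropped = set(X.columns) - set(keep)
    if dropped:
        log.info("dropping constant design columns: %s", sorted(dropped))
    X = X[keep]
    Xc = sm.add_constant(X, has_constant="add")
    separated = False
    try:
        import warnings as _warnings

        with np.errstate(all="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # separation detected below
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        params = res.params
        if not np.all(np.isfinite(params)) or np.abs(params).max() > 50:
            separated = True
    except Exception:
        separated = True
    if separated:
        if not allow_penalized:
            raise RuntimeError(
                f"model {spec.name!r}: (quasi-)separation detected; "
                "refit with allow_penalized=True"
            )
        from sklearn.linear_model import LogisticRegression

        # Weak ridge on standardized columns, mapped back to original scale.
        Xv = X.to_numpy()
        mu, sd = Xv.mean(axis=0), Xv.std(axis=0)
        sd[sd == 0] = 1.0
        clf = LogisticRegression(l1_ratio=0.0, C=10.0, max_iter=5000)
        clf.fit((Xv - mu) / sd, y)
        beta = clf.coef_[0] / sd
        intercept = float(clf.intercept_[0] - (beta * mu).sum())
        coefs = dict(zip(X.columns, map(float, beta)))
        return RiskModelSpec(spec.name, spec.covariates, intercept, coefs,
                             penalized=True)
    intercept = float(params["const"])
    coefs = {c: float(params[c]) for c in X.columns}
    return RiskModelSpec(spec.name, spec.covariates, intercept, coefs)


def _auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    r = rankdata(scores)
    return (r[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def roc_auc(scores, labels, n_boot: int = 2000, seed: int = 0,
            alpha: float = 0.05) -> tuple[float, float, float]:
    """Tie-averaged rank AUC with a stratified bootstrap percentile CI."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both outcome classes must be present")
    auc = _auc_rank(scores, labels)
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        p = rng.choice(pos_idx, size=len(pos_idx), replace=True)
        n = rng.choice(neg_idx, size=len(neg_idx), replace=True)
        idx = np.concatenate([p, n])
        boot[b] = _auc_rank(scores[idx], labels[idx])
    lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(auc), float(lo), float(hi)


def c_index(scores, labels) -> float:
    """Concordance probability for the binary endpoint (ties count 1/2).

    Identical to the rank AUC for a binary outcome; kept as a named
    operation because it is reported as Harrell's C for the nomogram.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both outcome classes must be present")
    return float(_auc_rank(scores, labels))


def hosmer_lemeshow(pred, obs, groups: int = 10
                    ) -> tuple[float, float, pd.DataFrame]:
    """Decile-of-risk Hosmer-Lemeshow goodness-of-fit test.

    Returns (chi2, p, calibration table with mean predicted vs observed
    rate per group).  Degrees of freedom = groups - 2 after any tie-driven
    group merging.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs).astype(float)
    if groups < 2:
        raise ValueError("need >= 2 groups")
    if pred.min() <= 0 or pred.max() >= 1:
        pred = np.clip(pred, 1e-10, 1 - 1e-10)
    try:
        bins = pd.qcut(pred, groups, duplicates="drop")
    except ValueError:
        bins = pd.qcut(rankdata(pred, method="average"), groups, duplicates="drop")
    df = pd.DataFrame({"pred": pred, "obs": obs, "bin": bins})
    tab = df.groupby("bin", observed=True).agg(
        n=("obs", "size"), observed=("obs", "sum"), mean_pred=("pred", "mean")
    ).reset_index(drop=True)
    g_eff = len(tab)
    if g_eff < groups:
        log.info("Hosmer-Lemeshow: %d groups merged into %d by ties", groups, g_eff)
    e1 = tab["n"] * tab["mean_pred"]
    o1 = tab["observed"]
    chi2 = float((((o1 - e1) ** 2) / (tab["n"] * tab["mean_pred"]
                                      * (1 - tab["mean_pred"]))).sum())
    # dof g-2 per the fitted-model reference distribution; tie-collapsed
    # degenerate groupings keep at least 1 dof (chi2 = 0 then gives p = 1).
    dof = max(g_eff - 2, 1)
    p = float(stats.chi2.sf(chi2, dof))
    tab["observed_rate"] = tab["observed"] / tab["n"]
    return chi2, p, tab[["n", "mean_pred", "observed_rate"]]


def build_nomogram(model: RiskModelSpec, table: pd.DataFrame) -> dict:
    """Points re-expression of a fitted logistic model.

    Each predictor's points are ``100 * |beta * (value - ref)| / M`` where
    ``M = max_j |beta_j * range_j|`` over the model's design columns and
    ``ref`` is the in-cohort minimum; total points map to probability via
    the logistic.  Returns per-predictor point tables and the
    total-points -> probability mapping.
    """
    if model.intercept is None:
        raise RuntimeError("model must be fitted first")
    X = encode_design(table, model.covariates)
    entries = []
    for col in X.columns:
        beta = model.coefficients.get(col, 0.0)
        lo, hi = float(X[col].min()), float(X[col].max())
        span = abs(beta * (hi - lo))
        if span == 0:
            log.info("nomogram: zero-range predictor %s excluded", col)
            continue
        entries.append((col, beta, lo, hi, span))
    if not entries:
        raise ValueError("no predictor with non-zero point range")
    m = max(e[4] for e in entries)
    scales = {}
    for col, beta, lo, hi, span in entries:
        ref = lo if beta > 0 else hi  # reference = end contributing least risk
        scales[col] = {
            "beta": beta,
            "ref": ref,
            "points_per_unit": 100.0 * abs(beta) / m,
            "max_points": 100.0 * span / m,
        }
    # Total-points <-> probability mapping: eta at reference + points * m/100.
    eta_ref = model.intercept + sum(
        s["beta"] * s["ref"] for s in scales.values()
    )
    total_grid = np.linspace(0, sum(s["max_points"] for s in scales.values()), 101)
    prob_grid = 1.0 / (1.0 + np.exp(-(eta_ref + total_grid * m / 100.0)))
    return {
        "predictors": scales,
        "eta_reference": float(eta_ref),
        "units_per_point": float(m / 100.0),
        "total_points": total_grid,
        "probability": prob_grid,
    }


def nomogram_probability(nomogram: dict, table: pd.DataFrame,
                         model: RiskModelSpec) -> np.ndarray:
    """Probability via the points pathway (for the round-trip property)."""
    X = encode_design(table, model.covariates)
    total = np.zeros(len(table))
    for col, s in nomogram["predictors"].items():
        total += s["points_per_unit"] * np.abs(X[col].to_numpy() - s["ref"])
    eta = nomogram["eta_reference"] + total * nomogram["units_per_point"]
    return 1.0 / (1.0 + np.exp(-eta))


def youden_cutoff(scores, labels) -> float:
    """Score threshold maximizing sensitivity + specificity - 1."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    thresholds = np.unique(scores)
    best_t, best_j = thresholds[0], -np.inf
    n1 = labels.sum()
    n0 = len(labels) - n1
    for t in thresholds:
        pred = scores >= t
        tpr = (pred & (labels == 1)).sum() / n1
        fpr = (pred & (labels == 0)).sum() / n0
        j = tpr - fpr
        if j > best_j:
            best_j, best_t = j, t
    return float(best_t)


def km_stratify(scores, survival_months, events, cutoff: float
                ) -> dict:
    """Kaplan-Meier curves and log-rank test for score-defined risk groups.

    ``events`` marks deaths (non-survivors, all before 60 months); patients
    alive at last follow-up are censored at their recorded time.  High
    score = low risk (higher scores indicate longer survival).
    """
    scores = np.asarray(scores, dtype=float)
    t = np.asarray(survival_months, dtype=float)
    e = np.asarray(events).astype(bool)
    if (t <= 0).any():
        raise ValueError("survival months must be positive")
    low_risk = scores >= cutoff
    if low_risk.sum() < 2 or (~low_risk).sum() < 2:
        raise ValueError("cutoff leaves < 2 patients in one risk group")
    curves = {}
    for name, sel in (("low_risk", low_risk), ("high_risk", ~low_risk)):
        km = KaplanMeierFitter()
        km.fit(t[sel], e[sel], label=name)
        curves[name] = km
    if e.sum() == 0:
        return {"curves": curves, "logrank_p": None, "cutoff": cutoff,
                "note": "no events in either group; log-rank not applicable"}
    lr = logrank_test(t[low_risk], t[~low_risk], e[low_risk], e[~low_risk])
    return {"curves": curves, "logrank_p": float(lr.p_value),
            "logrank_stat": float(lr.test_statistic), "cutoff": cutoff}


def fisher_exact_2xk(table: np.ndarray) -> float:
    """Two-sided exact Fisher p for a 2 x k contingency table.

    Exhaustive enumeration over tables with the observed margins under the
    multivariate hypergeometric null; the p-value sums the probabilities of
    all tables no more probable than the observed one.
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("expected a 2 x k table")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    col_tot = table.sum(axis=0)
    row1 = int(table.sum(axis=1)[0])
    k = table.shape[1]
    from math import comb

    def prob(cells: tuple[int, ...]) -> float:
        num = 1.0
        for c, n in zip(cells, col_tot):
            num *= comb(int(n), int(c))
        return num

    total_ways = comb(int(col_tot.sum()), row1)
    obs_p = prob(tuple(table[0]))
    p_sum = 0.0
    eps = 1e-9

    def rec(j: int, remaining: int, cells: list[int]):
        nonlocal p_sum
        if j == k - 1:
            if 0 <= remaining <= col_tot[j]:
                pr = prob(tuple(cells + [remaining]))
                if pr <= obs_p * (1 + eps):
                    p_sum += pr
            return
        tail_cap = int(col_tot[j + 1:].sum())
        lo = max(0, remaining - tail_cap)
        hi = min(int(col_tot[j]), remaining)
        for c in range(lo, hi + 1):
            rec(j + 1, remaining - c, cells + [c])

    rec(0, row1, [])
    return min(1.0, p_sum / total_ways)


def cohort_compare(table: pd.DataFrame, group_col: str = "os_5yr",
                   continuous: tuple[str, ...] = ("age", "cea", "dist_anal_verge",
                                                  "total_ln", "positive_ln", "lnr",
                                                  "survival_months"),
                   categorical: tuple[str, ...] = ("gender", "c_t", "c_n", "stage",
                                                   "tumor_deposit", "surgery",
                                                   "chemo", "location", "emvi",
                                                   "y_t", "y_n", "histology"),
                   ) -> pd.DataFrame:
    """Per-variable OS-vs-non-OS comparison: one-way ANOVA for continuous
    variables, exact Fisher (2 x k) for categoricals."""
    groups = table[group_col].astype(bool)
    if groups.nunique() < 2:
        raise ValueError("both groups must be present")
    rows = []
    for var in continuous:
        if var not in table:
            continue
        a = table.loc[groups, var].astype(float)
        b = table.loc[~groups, var].astype(float)
        if a.std() == 0 and b.std() == 0:
            rows.append((var, "anova", np.nan, None))
            continue
        f, p = stats.f_oneway(a, b)
        rows.append((var, "anova", float(f), float(p)))
    for var in categorical:
        if var not in table:
            continue
        ct = pd.crosstab(groups, table[var].astype(str))
        if ct.shape[1] < 2:
            rows.append((var, "fisher", np.nan, None))
            continue
        p = fisher_exact_2xk(ct.to_numpy())
        rows.append((var, "fisher", np.nan, float(p)))
    return pd.DataFrame(rows, columns=["variable", "test", "statistic", "p"])


def feature_clinical_heatmap(features: pd.DataFrame, clinical: pd.DataFrame
                             ) -> pd.DataFrame:
    """Spearman correlation matrix of selected features vs encoded clinical
    columns (constant columns masked as NaN); positive = green, negative =
    red in the standard rendering."""
    rho = pd.DataFrame(
        np.nan, index=features.columns, columns=clinical.columns, dtype=float
    )
    for f in features.columns:
        x = features[f].astype(float).to_numpy()
        for c in clinical.columns:
            y = clinical[c].astype(float).to_numpy()
            if x.std() == 0 or y.std() == 0:
                continue
            rho.loc[f, c] = float(stats.spearmanr(x, y).statistic)
    return rho
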