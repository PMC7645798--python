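"""Cluster–phenotype association statistics.

Baseline outcomes are tested with multinomial logistic regression (cluster
indicator as response, so skewed outcome distributions need no normality
assumption): an outcome's effect is a likelihood-ratio test of the model with
confounders + outcome against confounders alone, followed — on nominal
significance — by pairwise Wald tests of the outcome coefficient between
every cluster pair. Confounders are chosen beforehand by bidirectional
stepwise multinomial regression under AIC, starting from the null model.
All raw p-values of a study battery are jointly Benjamini–Hochberg adjusted.

Longitudinal outcomes are first converted to progression scores
((value − baseline value) / SD of the baseline values) and modelled per
cluster pair with a linear mixed model: fixed cluster, time and
cluster × time effects, a per-patient random intercept, maximum-likelihood
fitting, and the time coding (numeric vs categorical) chosen by AIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConfounderSelection",
    "AssociationResult",
    "ProgressionModelResult",
    "select_confounders",
    "outcome_association",
    "adjust_bh",
    "longitudinal_association",
    "progression_scores",
]


# ---------------------------------------------------------------------------
# multinomial helpers


def _design(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Numeric columns as-is; categoricals dummy-coded (first level dropped)."""
    parts = [pd.Series(1.0, index=df.index, name="const")]
    for col in columns:
        s = df[col]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float))
        else:
            dummies = pd.get_dummies(s.astype(str), prefix=col, drop_first=True)
            parts.append(dummies.astype(float))
    return pd.concat(parts, axis=1)


def _fit_mnlogit(y_codes: np.ndarray, X: pd.DataFrame):
    """Fit a multinomial logit; returns None on failure or quasi-separation."""
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.MNLogit(y_codes, X.to_numpy(dtype=float)).fit(
                method="newton", maxiter=200, disp=0
            )
        except Exception:
            return None
    if not np.isfinite(res.llf):
        return None
    if np.max(np.abs(res.params)) > 25:  # separation guard
        return None
    return res


@dataclass
class ConfounderSelection:
    """Outcome of the stepwise AIC confounder search."""

    candidates: list[str]
    selected: list[str]
    aic_trace: list[tuple[str, str, float]]  # (action, term, aic)


def select_confounders(
    labels, candidates: pd.DataFrame, max_steps: int = 50
) -> ConfounderSelection:
    """Bidirectional stepwise multinomial regression under AIC, from the null model.

    At each step the single add or drop move that most lowers the AIC is
    taken; the search stops when no move improves. Candidates that fail to
    fit (e.g. quasi-separated) are skipped with a warning.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 clusters")
    y = np.searchsorted(classes, labels)
    cand = list(candidates.columns)
    bad: set[str] = set()
    for col in cand:
        res = _fit_mnlogit(y, _design(candidates, [col]))
        if res is None:
            warnings.warn(f"confounder candidate {col!r} skipped (degenerate fit)", stacklevel=2)
            bad.add(col)
    cand = [c for c in cand if c not in bad]

    null_res = _fit_mnlogit(y, _design(candidates, []))
    if null_res is None:
        raise RuntimeError("null multinomial model failed to fit")
    current: list[str] = []
    current_aic = null_res.aic
    trace = [("start", "<null>", float(current_aic))]
    for _ in range(max_steps):
        moves: list[tuple[float, str, str]] = []
        for col in cand:
            if col in current:
                trial = [c for c in current if c != col]
                action = "drop"
            else:
                trial = current + [col]
                action = "add"
            res = _fit_mnlogit(y, _design(candidates, trial))
            if res is not None:
                moves.append((float(res.aic), action, col))
        if not moves:
            break
        best_aic, action, col = min(moves)
        if best_aic >= current_aic - 1e-9:
            break
        current = [c for c in current if c != col] if action == "drop" else current + [col]
        current_aic = best_aic
        trace.append((action, col, best_aic))
    return ConfounderSelection(candidates=list(candidates.columns), selected=current, aic_trace=trace)


@dataclass
class AssociationResult:
    """LRT + pairwise Wald tests of one outcome against cluster membership."""

    outcome: str
    lrt_stat: float
    lrt_df: int
    lrt_p: float
    pairwise_wald_p: dict[tuple, float]  # (cluster_a, cluster_b) -> raw p
    aic: float
    converged: bool = True
    adjusted_p: dict = field(default_factory=dict)  # filled by the caller after BH


def outcome_association(
    outcome: pd.Series,
    labels,
    confounders: pd.DataFrame | None = None,
) -> AssociationResult:
    """Test one outcome's association with cluster membership.

    Fits cluster ~ confounders + outcome (multinomial) against
    cluster ~ confounders; the likelihood-ratio statistic has k−1 degrees of
    freedom. On nominal LRT significance (p < 0.05), Wald tests compare the
    outcome coefficient between every cluster pair.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    k = len(classes)
    if k < 2:
        raise ValueError("need at least 2 clusters")
    for cls, cnt in zip(*np.unique(labels, return_counts=True)):
        if cnt < 5:
            warnings.warn(f"cluster {cls!r} has fewer than 5 patients", stacklevel=2)
    y = np.searchsorted(classes, labels)
    name = outcome.name or "outcome"
    df = pd.DataFrame({name: np.asarray(outcome, dtype=float)})
    conf_cols: list[str] = []
    if confounders is not None and len(confounders.columns):
        for col in confounders.columns:
            df[col] = np.asarray(confounders[col])
        conf_cols = list(confounders.columns)
    keep = ~df[name].isna()
    df, y = df[keep.to_numpy()], y[keep.to_numpy()]

    X_full = _design(df, conf_cols + [name])
    X_null = _design(df, conf_cols)
    res_full = _fit_mnlogit(y, X_full)
    res_null = _fit_mnlogit(y, X_null)
    if res_full is None or res_null is None:
        warnings.warn(f"outcome {name!r}: non-convergent fit; excluded from BH family", stacklevel=2)
        return AssociationResult(
            outcome=name, lrt_stat=float("nan"), lrt_df=k - 1, lrt_p=float("nan"),
            pairwise_wald_p={}, aic=float("nan"), converged=False,
        )
    lrt = 2.0 * (res_full.llf - res_null.llf)
    lrt = max(lrt, 0.0)
    lrt_p = float(sps.chi2.sf(lrt, k - 1))

    pairwise: dict[tuple, float] = {}
    if lrt_p < 0.05:
        # coefficient of the outcome term per non-baseline class
        var_idx = list(X_full.columns).index(name)
        K = X_full.shape[1]
        params = np.asarray(res_full.params)  # (K, k-1)
        cov = np.asarray(res_full.cov_params())  # ((k-1)*K, (k-1)*K), equation-major
        betas = np.concatenate([[0.0], params[var_idx, :]])  # baseline first

        def flat(eq: int) -> int:
            return eq * K + var_idx

        k_eq = k - 1
        var = np.zeros(k)
        covmat = np.zeros((k, k))
        for a in range(1, k):
            var[a] = cov[flat(a - 1), flat(a - 1)]
            for b in range(1, k):
                covmat[a, b] = cov[flat(a - 1), flat(b - 1)]
        del k_eq
        for ia in range(k):
            for ib in range(ia + 1, k):
                diff = betas[ia] - betas[ib]
                v = var[ia] + var[ib] - 2.0 * covmat[ia, ib]
                if v <= 0:
                    p = float("nan")
                else:
                    z = diff / np.sqrt(v)
                    p = float(2.0 * sps.norm.sf(abs(z)))
                pairwise[(classes[ia], classes[ib])] = p
    return AssociationResult(
        outcome=name,
        lrt_stat=float(lrt),
        lrt_df=k - 1,
        lrt_p=lrt_p,
        pairwise_wald_p=pairwise,
        aic=float(res_full.aic),
    )


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (clipped at 1, monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("p-values contain NaN")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# longitudinal models


def progression_scores(
    visit_table: pd.DataFrame, outcome: str, patient_col: str = "patient_id",
    visit_col: str = "visit",
) -> pd.DataFrame:
    """Baseline-normalized progression score per patient-visit.

    score = (value − patient's baseline value) / SD of baseline values across
    patients. The baseline visit scores exactly 0 for every patient.
    """
    df = visit_table[[patient_col, visit_col, outcome]].copy()
    base_visit = df[visit_col].min()
    baseline = df[df[visit_col] == base_visit].set_index(patient_col)[outcome]
    sd0 = float(baseline.std(ddof=1))
    if sd0 == 0 or np.isnan(sd0):
        sd0 = 1.0
    df["progression"] = (
        df[outcome].to_numpy() - baseline.reindex(df[patient_col]).to_numpy()
    ) / sd0
    return df


@dataclass
class ProgressionModelResult:
    """Mixed-model comparison of progression between one cluster pair."""

    outcome: str
    cluster_pair: tuple
    time_coding: str  # "numeric" or "categorical"
    aic_numeric: float
    aic_categorical: float
    fixed_effects: dict[str, float]
    random_intercept_var: float
    cluster_lrt_stat: float
    cluster_lrt_df: int
    cluster_lrt_p: float
    fallback_ols: bool = False


def _fit_mixed(formula: str, data: pd.DataFrame, groups: pd.Series):
    import statsmodels.formula.api as smf

    last_exc: Exception | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "bfgs", "powell", "cg"):
            model = smf.mixedlm(formula, data, groups=groups)
            try:
                return model.fit(reml=False, method=method, maxiter=200)
            except Exception as exc:  # singular hessian etc.; try next optimizer
                last_exc = exc
    raise RuntimeError(f"mixed-model fit failed: {last_exc}")


def longitudinal_association(
    visit_table: pd.DataFrame,
    labels: pd.Series,
    outcome: str,
    cluster_pair: tuple,
    patient_col: str = "patient_id",
    visit_col: str = "visit",
) -> ProgressionModelResult:
    """Random-intercept mixed model of progression for one cluster pair.

    Fixed effects: cluster, time, cluster × time; per-patient random
    intercept; ML fitting. Time enters either numerically or categorically,
    chosen by AIC. The cluster effect (main + interaction jointly) is tested
    by a likelihood-ratio test against the time-only model. A singular
    random-effects fit falls back to ordinary least squares with a warning.
    """
    df = progression_scores(visit_table, outcome, patient_col, visit_col)
    # baseline rows are identically zero by construction and carry no
    # information; keeping them forces the random-intercept variance onto
    # the boundary, so the model is fit on post-baseline visits only
    df = df[df[visit_col] > df[visit_col].min()].reset_index(drop=True)
    lab = labels.reindex(df[patient_col]).to_numpy()
    keep = np.isin(lab, list(cluster_pair))
    df = df.loc[keep].reset_index(drop=True)
    lab = lab[keep]
    if len(np.unique(lab)) < 2:
        raise ValueError("both clusters of the pair must be represented")
    n_visits = df.groupby(patient_col)[visit_col].nunique().min()
    if n_visits < 2:
        raise ValueError("need at least 2 visits per patient")
    df["cluster"] = (lab == cluster_pair[1]).astype(float)
    df["time_num"] = df[visit_col].astype(float)
    df["time_cat"] = df[visit_col].astype(str)

    fallback = False
    results = {}
    try:
        res_num = _fit_mixed("progression ~ cluster * time_num", df, df[patient_col])
        res_cat = _fit_mixed("progression ~ cluster * C(time_cat)", df, df[patient_col])
        results["numeric"] = res_num
        results["categorical"] = res_cat
        aic_num, aic_cat = float(res_num.aic), float(res_cat.aic)
    except Exception:
        fallback = True
        aic_num = aic_cat = float("nan")

    if not fallback:
        coding = "numeric" if aic_num <= aic_cat else "categorical"
        res = results[coding]
        time_term = "time_num" if coding == "numeric" else "C(time_cat)"
        try:
            res_null = _fit_mixed(f"progression ~ {time_term}", df, df[patient_col])
        except Exception:
            fallback = True
        if not fallback:
            lrt = max(2.0 * (res.llf - res_null.llf), 0.0)
            df_diff = len(res.fe_params) - len(res_null.fe_params)
            ri_var = float(np.asarray(res.cov_re).ravel()[0])
            fixed = {k: float(v) for k, v in res.fe_params.items()}
            return ProgressionModelResult(
                outcome=outcome,
                cluster_pair=cluster_pair,
                time_coding=coding,
                aic_numeric=aic_num,
                aic_categorical=aic_cat,
                fixed_effects=fixed,
                random_intercept_var=ri_var,
                cluster_lrt_stat=float(lrt),
                cluster_lrt_df=df_diff,
                cluster_lrt_p=float(sps.chi2.sf(lrt, max(df_diff, 1))),
            )

    warnings.warn("singular mixed-model fit; falling back to fixed-effects OLS", stacklevel=2)
    import statsmodels.formula.api as smf

    res_num = smf.ols("progression ~ cluster * time_num", df).fit()
    res_cat = smf.ols("progression ~ cluster * C(time_cat)", df).fit()
    coding = "numeric" if res_num.aic <= res_cat.aic else "categorical"
    res = res_num if coding == "numeric" else res_cat
    time_term = "time_num" if coding == "numeric" else "C(time_cat)"
    res_null = smf.ols(f"progression ~ {time_term}", df).fit()
    lrt = max(2.0 * (res.llf - res_null.llf), 0.0)
    df_diff = int(res.df_model - res_null.df_model)
    return ProgressionModelResult(
        outcome=outcome,
        cluster_pair=cluster_pair,
        time_coding=coding,
        aic_numeric=float(res_num.aic),
        aic_categorical=float(res_cat.aic),
        fixed_effects={k: float(v) for k, v in res.params.items()},
        random_intercept_var=0.0,
        cluster_lrt_stat=float(lrt),
        cluster_lrt_df=df_diff,
        cluster_lrt_p=float(sps.chi2.sf(lrt, max(df_diff, 1))),
        fallback_ols=True,
    )
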