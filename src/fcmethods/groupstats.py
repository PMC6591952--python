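"""Mass-univariate covariate-adjusted group comparison and selection.

Each feature is regressed on a group indicator plus nuisance covariates
(age, sex, mean head motion, site indicators) by ordinary least
squares; the group coefficient's two-sided t test gives the
per-feature p value, corrected across features by Benjamini-Hochberg
FDR.  Feature selection keeps features with uncorrected p below alpha,
excluding by rule the families that yield a single scalar per subject.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .features import SCALAR_METHODS, FeatureTable

STANDARD_COVARIATES = ("age", "sex", "motion", "site")

#: phenotype column backing each covariate name
_COVARIATE_COLUMNS = {"age": "age", "sex": "sex", "motion": "mean_fd",
                      "site": "site", "pct_motion_free": "pct_motion_free"}


def design_matrix(phenotypes: pd.DataFrame,
                  covariates=STANDARD_COVARIATES,
                  group_col: str = "group",
                  autism_label: str = "autism") -> pd.DataFrame:
    """Intercept + group indicator + covariate columns.

    The group indicator is 1 for the autism group, so the group beta
    is the autism-minus-control difference in feature units.  Site
    enters as indicator contrasts (first site as reference); sex as a
    male indicator.  The ``motion`` covariate uses mean framewise
    displacement; ``pct_motion_free`` is the documented alternative
    regressor (fraction of retained volumes).
    """
    cols = {"intercept": np.ones(len(phenotypes)),
            "group": (phenotypes[group_col] == autism_label).astype(float)}
    for cov in covariates:
        col = _COVARIATE_COLUMNS.get(cov, cov)
        if col not in phenotypes.columns:
            raise KeyError(f"covariate column {col!r} not in phenotypes")
        if cov == "sex":
            cols["sex_male"] = (phenotypes[col] == "M").astype(float)
        elif cov == "site":
            sites = sorted(phenotypes[col].unique())
            for s in sites[1:]:
                cols[f"site_{s}"] = (phenotypes[col] == s).astype(float)
        else:
            cols[cov] = phenotypes[col].astype(float).to_numpy()
    return pd.DataFrame(cols, index=phenotypes.index)


def _ols_group_stats(X: np.ndarray, Y: np.ndarray):
    """OLS of each column of Y on X; stats for X's column 1 (group).

    Returns (beta, t, p, df) arrays over features; assumes complete
    data and full-rank X.
    """
    n, k = X.shape
    df = n - k
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = xtx_inv @ X.T @ Y                      # (k, F)
    resid = Y - X @ coef
    rss = (resid ** 2).sum(axis=0)
    sigma2 = rss / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    beta = coef[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    degenerate = se == 0
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, 2.0 * stats.t.sf(np.abs(t), df))
    return beta, t, p, df, degenerate


class MassUnivariateGLM(BaseEstimator):
    """Per-feature group-difference GLM with covariate adjustment.

    Parameters
    ----------
    covariates
        Subset of {age, sex, motion, site} (plus ``pct_motion_free``
        as an alternative motion regressor).
    alpha, q_level
        Selection and FDR thresholds.

    After ``fit(features, phenotypes)`` the per-feature results live
    in ``results_`` (feature_id, method, beta, t, p, q, df, n_used,
    note).
    """

    def __init__(self, covariates=STANDARD_COVARIATES, alpha=0.05,
                 q_level=0.05, group_col="group", autism_label="autism"):
        self.covariates = covariates
        self.alpha = alpha
        self.q_level = q_level
        self.group_col = group_col
        self.autism_label = autism_label

    def fit(self, features: FeatureTable | pd.DataFrame,
            phenotypes: pd.DataFrame, y=None):
        values = features.values if isinstance(features, FeatureTable) \
        else features
        methods = (features.methods if isinstance(features, FeatureTable)
                   else pd.Series("unknown", index=values.columns))
        phen = phenotypes.set_index("subject") \
            if "subject" in phenotypes.columns else phenotypes
        phen = phen.loc[values.index]
        design = design_matrix(phen, self.covariates, self.group_col,
                               self.autism_label)
        X_full = design.to_numpy(float)
        cov_ok = np.isfinite(X_full).all(axis=1)
        Y_all = values.to_numpy(float)
        rows = []
        # group features by missing-data pattern so each pattern is
        # solved in one vectorized pass
        miss = ~np.isfinite(Y_all)
        patterns: dict[bytes, list[int]] = {}
        for f_i in range(Y_all.shape[1]):
            key = (miss[:, f_i] | ~cov_ok).tobytes()
            patterns.setdefault(key, []).append(f_i)
        n_sub = Y_all.shape[0]
        for key, f_idx in patterns.items():
            keep = ~np.frombuffer(key, dtype=bool).copy()
            X = X_full[keep]
            Y = Y_all[np.ix_(keep, f_idx)]
            n_used = int(keep.sum())
            groups = X[:, 1]
            err = None
            if n_used - X.shape[1] < 1:
                err = "insufficient degrees of freedom"
            elif min((groups == 1).sum(), (groups == 0).sum()) < 2:
                err = "fewer than 2 subjects in a group"
            elif np.linalg.matrix_rank(X) < X.shape[1]:
                err = "rank-deficient design"
            if err is not None:
                for f_i in f_idx:
                    rows.append((f_i, np.nan, np.nan, np.nan,
                                 n_used - X.shape[1], n_used, err))
                continue
            beta, t, p, df, degen = _ols_group_stats(X, Y)
            for b, tt, pp, dg, f_i in zip(beta, t, p, degen, f_idx):
                note = "degenerate variance" if dg else ""
                rows.append((f_i, b, tt, pp, df, n_used, note))
        rows.sort(key=lambda r: r[0])
        res = pd.DataFrame(rows, columns=["_i", "beta", "t", "p", "df",
                                          "n_used", "note"])
        res.insert(0, "feature_id", values.columns[res.pop("_i")])
        res.insert(1, "method",
                   methods.reindex(res["feature_id"]).to_numpy())
        res["q"] = fdr_bh(res["p"].to_numpy(), self.q_level)[0]
        self.results_ = res
        self.model_spec_ = {"covariates": tuple(self.covariates)}
        self.n_features_in_ = Y_all.shape[1]
        self.n_subjects_ = n_sub
        return self

    def selected_(self) -> pd.DataFrame:
        """Rows passing the uncorrected-p selection rule."""
        res = self.results_
        keep = (res["p"] < self.alpha) & ~res["method"].isin(SCALAR_METHODS)
        return res[keep]


def glm_group_difference(features, phenotypes,
                         covariates=STANDARD_COVARIATES,
                         **kwargs) -> pd.DataFrame:
    """Per-feature group GLM results (thin wrapper over the estimator)."""
    model = MassUnivariateGLM(covariates=covariates, **kwargs)
    return model.fit(features, phenotypes).results_


def fdr_bh(p_values, q_level: float = 0.05):
    """Benjamini-Hochberg step-up adjusted q values and rejection mask.

    Missing p values are excluded from the family size m and get
    missing q values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    valid = np.isfinite(p)
    if np.any((p[valid] < 0) | (p[valid] > 1)):
        raise ValueError("p values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    reject = np.zeros(p.shape, dtype=bool)
    if valid.any():
        rej_v, q_v = multipletests(p[valid], alpha=q_level,
                                   method="fdr_bh")[:2]
        q[valid] = q_v
        reject[valid] = rej_v
    return q, reject


def combine_and_correct(results: list[pd.DataFrame],
                        cohorts: list[str] | None = None,
                        q_level: float = 0.05) -> pd.DataFrame:
    """Pool p values across cohorts into one family and re-correct.

    Returns the stacked result table with a ``cohort`` column and
    pooled-family ``q`` values.
    """
    if cohorts is None:
        cohorts = [f"cohort_{i}" for i in range(len(results))]
    tagged = []
    for tab, name in zip(results, cohorts):
        tab = tab.copy()
        tab["cohort"] = name
        tagged.append(tab)
    pooled = pd.concat(tagged, ignore_index=True)
    pooled["q"] = fdr_bh(pooled["p"].to_numpy(), q_level)[0]
    return pooled


def select_features(result: pd.DataFrame, features: FeatureTable,
                    alpha: float = 0.05) -> FeatureTable:
    """Keep features with p < alpha, excluding scalar-only methods.

    The inequality is strict; families yielding one value per subject
    (idiosyncrasy, modularity, global efficiency) never enter the
    selection pool.
    """
    keep = result[(result["p"] < alpha)
                  & ~result["method"].isin(SCALAR_METHODS)]
    return features.subset(keep["feature_id"].tolist())


def residualize(features: FeatureTable | pd.DataFrame,
                phenotypes: pd.DataFrame,
                nuisance=("site", "age", "sex", "motion")) -> pd.DataFrame:
    """Regress nuisance covariates out of every feature column.

    Least-squares residuals with the feature mean re-added (the
    intercept is retained), computed per missing-data pattern;
    missing entries stay missing.
    """
    values = features.values if isinstance(features, FeatureTable) \
        else features
    phen = phenotypes.set_index("subject") \
        if "subject" in phenotypes.columns else phenotypes
    phen = phen.loc[values.index]
    design = design_matrix(phen, nuisance).drop(columns="group")
    X_full = design.to_numpy(float)
    cov_ok = np.isfinite(X_full).all(axis=1)
    Y_all = values.to_numpy(float)
    out = np.full(Y_all.shape, np.nan)
    miss = ~np.isfinite(Y_all)
    patterns: dict[bytes, list[int]] = {}
    for f_i in range(Y_all.shape[1]):
        key = (miss[:, f_i] | ~cov_ok).tobytes()
        patterns.setdefault(key, []).append(f_i)
    for key, f_idx in patterns.items():
        keep = ~np.frombuffer(key, dtype=bool).copy()
        if keep.sum() <= X_full.shape[1]:
            warnings.warn("too few complete cases to residualize "
                          f"{len(f_idx)} feature(s); left missing",
                          stacklevel=2)
            continue
        X = X_full[keep]
        Y = Y_all[np.ix_(keep, f_idx)]
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ coef
        out[np.ix_(keep, f_idx)] = resid + Y.mean(axis=0)
    return pd.DataFrame(out, index=values.index, columns=values.columns)
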