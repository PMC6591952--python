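"""Integrative analyses across feature families and research sites.

Covers the cross-feature correlation structure (and its thresholded
graph), per-method feature averaging, behavior correlations, and the
leave-one-site-out generalizability analysis with partial correlations
against seven demographic/technical site factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from . import qc
from .features import FeatureTable
from .groupstats import MassUnivariateGLM

GENERALIZABILITY_FACTORS = ("mean_age", "sex_ratio", "mean_fd",
                            "pct_motion_free", "eyes_open_frac", "tr",
                            "n_subjects")


def feature_correlation_matrix(features: FeatureTable | pd.DataFrame,
                               subjects=None):
    """Across-subject Pearson correlations between feature columns.

    Pairwise-complete over missing values; returns ``(corr, n)`` with
    the per-cell complete-pair count.  ``subjects`` optionally
    restricts the rows (e.g. the autism group).
    """
    values = features.values if isinstance(features, FeatureTable) \
        else features
    if subjects is not None:
        values = values.loc[subjects]
    if len(values) < 3:
        raise ValueError("need at least 3 subjects")
    corr = values.corr(method="pearson")  # pairwise-complete
    notna = values.notna().to_numpy(float)
    n = pd.DataFrame(notna.T @ notna, index=values.columns,
                     columns=values.columns).astype(int)
    return corr, n


@dataclass
class FeatureGraph:
    """Features as nodes, edges where |across-subject r| > threshold."""

    graph: nx.Graph
    threshold: float

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(a, b, d["r"]) for a, b, d in self.graph.edges(data=True)]

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges,
                            columns=["feature_a", "feature_b", "r"])


def build_feature_graph(corr: pd.DataFrame, threshold: float = 0.4,
                        methods: pd.Series | None = None) -> FeatureGraph:
    """Threshold the feature correlation matrix into a graph.

    An edge is kept iff |r| strictly exceeds the threshold; nodes
    carry their method tag when provided.
    """
    g = nx.Graph()
    for f in corr.columns:
        g.add_node(f, method=(methods.get(f, "") if methods is not None
                              else ""))
    cols = list(corr.columns)
    mat = corr.to_numpy(float)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = mat[i, j]
            if np.isfinite(r) and abs(r) > threshold:
                g.add_edge(cols[i], cols[j], r=float(r))
    return FeatureGraph(graph=g, threshold=threshold)


def method_average(features: FeatureTable) -> pd.DataFrame:
    """Per-subject mean of each method's non-missing features."""
    methods = features.methods
    out = {}
    for method in dict.fromkeys(methods):          # preserve order
        cols = methods.index[methods == method]
        out[method] = features.values[cols].mean(axis=1, skipna=True)
    return pd.DataFrame(out, index=features.values.index)


def behavior_correlations(features: pd.DataFrame | FeatureTable,
                          behaviors: pd.DataFrame):
    """Unthresholded feature-by-behavior Pearson correlations.

    Pairwise-complete; returns ``(r, n)`` DataFrames indexed by
    feature with one column per behavior score.
    """
    values = features.values if isinstance(features, FeatureTable) \
        else features
    behaviors = behaviors.loc[values.index]
    r = pd.DataFrame(index=values.columns, columns=behaviors.columns,
                     dtype=float)
    n = pd.DataFrame(0, index=values.columns, columns=behaviors.columns)
    for b in behaviors.columns:
        bv = behaviors[b].to_numpy(float)
        for f in values.columns:
            fv = values[f].to_numpy(float)
            ok = np.isfinite(bv) & np.isfinite(fv)
            n.loc[f, b] = int(ok.sum())
            if ok.sum() >= 3 and fv[ok].std() > 0 and bv[ok].std() > 0:
                r.loc[f, b] = float(np.corrcoef(fv[ok], bv[ok])[0, 1])
    return r, n


# ---------------------------------------------------------------------------
# leave-one-site-out generalizability
# ---------------------------------------------------------------------------

@dataclass
class GeneralizabilityReport:
    """Per-site generalizability and the seven site factors.

    ``table`` has one row per site: r_gen (correlation between the
    site's per-feature group-difference t vector and the held-out
    remainder's), n_site, and the factor columns.
    """

    table: pd.DataFrame

    @property
    def factors(self) -> pd.DataFrame:
        return self.table[list(GENERALIZABILITY_FACTORS)]


def site_factor_table(cohort, fd_threshold: float = qc.FD_THRESHOLD_MM) \
        -> pd.DataFrame:
    """Demographic/technical factors per site.

    Eye status is encoded as the per-site fraction of eyes-open
    acquisitions; percent motion-free is the mean retained-volume
    fraction under the censoring rule.
    """
    rows = {}
    for site in cohort.sites:
        subs = [s for s in cohort.subjects if s.site == site]
        fracs = [qc.censor_volumes(s.fd_trace, fd_threshold).frac_kept
                 for s in subs]
        rows[site] = dict(
            mean_age=float(np.mean([s.age for s in subs])),
            sex_ratio=float(np.mean([s.sex == "M" for s in subs])),
            mean_fd=float(np.mean([s.mean_fd for s in subs])),
            pct_motion_free=float(np.mean(fracs)),
            eyes_open_frac=float(np.mean([s.eye_status == "open"
                                          for s in subs])),
            tr=float(np.mean([s.tr for s in subs])),
            n_subjects=len(subs),
        )
    return pd.DataFrame(rows).T


def site_generalizability(features: FeatureTable, phenotypes: pd.DataFrame,
                          cohort=None,
                          covariates=("age", "sex", "motion"),
                          min_per_group: int = 2) -> GeneralizabilityReport:
    """Leave-one-site-out comparison of per-feature t vectors.

    For each site, the group GLM is run within the site (without the
    site covariate) and within the pooled remainder (with site
    indicators); r_gen is the Pearson correlation of the two
    per-feature t vectors over features with finite statistics in
    both.  Sites failing the per-group minimum are skipped with a
    warning.  When ``cohort`` is given, the factor columns are filled
    from :func:`site_factor_table`.
    """
    phen = phenotypes.set_index("subject") \
        if "subject" in phenotypes.columns else phenotypes
    phen = phen.loc[features.values.index]
    sites = sorted(phen["site"].unique())
    if len(sites) < 3:
        raise ValueError("need at least 3 sites")
    covariates = tuple(c for c in covariates if c != "site")
    factor_tab = (site_factor_table(cohort) if cohort is not None
                  else None)
    rows = []
    for site in sites:
        in_site = phen["site"] == site
        site_groups = phen.loc[in_site, "group"].value_counts()
        if (len(site_groups) < 2
                or site_groups.min() < min_per_group):
            warnings.warn(f"site {site}: fewer than {min_per_group} "
                          "subjects per group; skipped", stacklevel=2)
            continue
        sub_site = features.values.index[in_site.to_numpy()]
        sub_rest = features.values.index[~in_site.to_numpy()]
        t_site = MassUnivariateGLM(covariates=covariates).fit(
            _subset_rows(features, sub_site),
            phen.loc[sub_site]).results_.set_index("feature_id")["t"]
        t_rest = MassUnivariateGLM(covariates=covariates + ("site",)).fit(
            _subset_rows(features, sub_rest),
            phen.loc[sub_rest]).results_.set_index("feature_id")["t"]
        ok = np.isfinite(t_site) & np.isfinite(t_rest)
        r_gen = (float(np.corrcoef(t_site[ok], t_rest[ok])[0, 1])
                 if ok.sum() >= 3 else np.nan)
        row = dict(site=site, r_gen=r_gen, n_site=int(in_site.sum()),
                   n_features=int(ok.sum()))
        if factor_tab is not None:
            row.update(factor_tab.loc[site].to_dict())
        rows.append(row)
    table = pd.DataFrame(rows).set_index("site")
    return GeneralizabilityReport(table=table)


def _subset_rows(features: FeatureTable, index) -> FeatureTable:
    return FeatureTable(values=features.values.loc[index],
                        definitions=features.definitions)


def _residuals(y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(y)), Z])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def partial_correlation(x, y, controls) -> float:
    """Partial Pearson correlation of x and y given control columns,
    by double residualization."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    Z = np.asarray(controls, float)
    if Z.ndim == 1:
        Z = Z[:, None]
    rx = _residuals(x, Z)
    ry = _residuals(y, Z)
    return float(np.corrcoef(rx, ry)[0, 1])


def factor_partial_correlations(report: GeneralizabilityReport) \
        -> pd.DataFrame:
    """Partial correlation of r_gen with each site factor.

    Each factor is partialled against the remaining six (dropping any
    with zero variance across sites, with a warning); p values come
    from the t transform with df = n_sites - n_factors - 1.  With too
    few sites the function falls back to marginal correlations.
    """
    tab = report.table.dropna(subset=["r_gen"])
    n_sites = len(tab)
    r_gen = tab["r_gen"].to_numpy(float)
    factors = {f: tab[f].to_numpy(float)
               for f in GENERALIZABILITY_FACTORS}
    usable = {f: v for f, v in factors.items() if np.std(v) > 0}
    dropped = sorted(set(factors) - set(usable))
    if dropped:
        warnings.warn("factor(s) with zero variance across sites "
                      f"dropped from the controlling set: {dropped}",
                      stacklevel=2)
    k = len(GENERALIZABILITY_FACTORS)
    marginal_only = n_sites <= len(usable) + 1
    if marginal_only:
        warnings.warn("too few sites for partial correlations; "
                      "reporting marginal correlations", stacklevel=2)
    rows = []
    for f in GENERALIZABILITY_FACTORS:
        if f not in usable:
            rows.append((f, np.nan, np.nan))
            continue
        if marginal_only:
            r = float(np.corrcoef(usable[f], r_gen)[0, 1])
        else:
            controls = np.column_stack(
                [v for g, v in usable.items() if g != f])
            r = partial_correlation(usable[f], r_gen, controls)
        df = n_sites - k - 1
        if df > 0 and abs(r) < 1:
            t = r * np.sqrt(df / (1 - r ** 2))
            p = float(2 * stats.t.sf(abs(t), df))
        else:
            p = np.nan
        rows.append((f, r, p))
    return pd.DataFrame(rows, columns=["factor", "partial_r", "p"]) \
        .set_index("factor")
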