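"""Configuration, cohort IO, and the end-to-end analysis pipeline.

The pipeline chains motion QC -> connectivity -> feature extraction ->
mass-univariate group GLMs (pooled and per site) -> FDR and feature
selection -> nuisance residualization -> cross-method analyses
(feature correlation graph, method averages, behavior correlations,
leave-one-site-out generalizability).  All inputs and outputs are
plain-text tabular files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, qc
from .atlas import RegionAtlas, read_atlas, write_atlas
from .crossmethod import (build_feature_graph, behavior_correlations,
                          factor_partial_correlations,
                          feature_correlation_matrix, method_average,
                          site_generalizability)
from .features import (ALL_METHODS, ConnectivityFeatureExtractor,
                       FeatureTable, ReferenceProfile)
from .groupstats import (MassUnivariateGLM, combine_and_correct,
                         select_features)
from .synth import CohortDataset, SubjectRecord

log = logging.getLogger("fcmethods")


@dataclass
class RunConfig:
    """All pipeline knobs; defaults follow the reference analysis."""

    cohort_dir: str | None = None
    atlas_path: str | None = None
    profile_path: str | None = None
    out_dir: str | None = None
    fd_threshold_mm: float = 0.3
    min_frac_kept: float = 0.5
    strength_lo: float = -0.2
    strength_hi: float = 0.6
    strength_width: float = 0.02
    euclid_width: float = 5.0
    euclid_max: float = 165.0
    path_width: float = 50.0
    path_max: float = 500.0
    eval_lag_seconds: float = 6.0
    covariates: tuple = ("age", "sex", "motion", "site")
    alpha: float = 0.05
    q_level: float = 0.05
    graph_threshold: float = 0.4
    methods: tuple = ALL_METHODS
    n_modularity_restarts: int = 10
    seed: int = 0

    def __post_init__(self):
        for name in ("fd_threshold_mm", "min_frac_kept", "strength_width",
                     "euclid_width", "path_width", "alpha", "q_level",
                     "graph_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["covariates"] = list(d["covariates"])
        d["methods"] = list(d["methods"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("covariates", "methods"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# cohort IO (plain-text layout)
# ---------------------------------------------------------------------------

def write_cohort(cohort: CohortDataset, out_dir,
                 profile: ReferenceProfile | None = None) -> Path:
    """Write a cohort in the standard layout; returns the manifest path.

    Layout: ``atlas.tsv``, ``phenotypes.csv``, one ``<subject>_ts.tsv``
    (time x ROI, header of region names) and ``<subject>_fd.txt`` per
    subject, optionally ``profile_mean_conn.tsv`` +
    ``profile_path_lengths.tsv``, and a ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_atlas(cohort.atlas, out / "atlas.tsv")
    phen = cohort.phenotype_frame()
    phen.to_csv(out / "phenotypes.csv", index=False)
    names = [r.name for r in cohort.atlas.regions]
    series_files, fd_files = {}, {}
    for s in cohort.subjects:
        ts_file = f"{s.subject_id}_ts.tsv"
        pd.DataFrame(s.timeseries, columns=names).to_csv(
            out / ts_file, sep="\t", index=False, float_format="%.6g")
        fd_file = f"{s.subject_id}_fd.txt"
        np.savetxt(out / fd_file, s.fd_trace, fmt="%.6g")
        series_files[s.subject_id] = ts_file
        fd_files[s.subject_id] = fd_file
    manifest = dict(atlas="atlas.tsv", phenotypes="phenotypes.csv",
                    series=series_files, fd=fd_files,
                    provenance=cohort.provenance)
    if profile is not None:
        pd.DataFrame(profile.mean_conn).to_csv(
            out / "profile_mean_conn.tsv", sep="\t", index=False,
            header=False, float_format="%.8g")
        profile.path_lengths.to_csv(out / "profile_path_lengths.tsv",
                                    sep="\t", index=False)
        manifest["profile_mean_conn"] = "profile_mean_conn.tsv"
        manifest["profile_path_lengths"] = "profile_path_lengths.tsv"
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def _read_series(path: Path, names: list[str]) -> np.ndarray:
    """Load a series TSV in either orientation to (T, R) atlas order.

    time x ROI files carry a header row of region names; ROI x time
    files carry the region names in the first column (no header row).
    """
    df = pd.read_csv(path, sep="\t")
    if set(df.columns) >= set(names):
        return df[names].to_numpy(float)          # time x ROI
    df = pd.read_csv(path, sep="\t", header=None, index_col=0)
    if set(df.index) >= set(names):
        return df.loc[names].to_numpy(float).T    # ROI x time
    raise ValueError(
        f"{path}: neither header nor first column matches atlas "
        "region names")


def read_cohort(manifest_path) -> tuple[CohortDataset,
                                        ReferenceProfile | None]:
    """Load a cohort (and profile, when present) from its manifest."""
    mpath = Path(manifest_path)
    root = mpath.parent
    manifest = json.loads(mpath.read_text())
    atlas = read_atlas(root / manifest["atlas"])
    names = [r.name for r in atlas.regions]
    phen = pd.read_csv(root / manifest["phenotypes"])
    series = manifest["series"]
    missing = sorted(set(phen["subject"]) ^ set(series))
    if missing:
        raise ValueError(
            f"phenotype/series subject-id mismatch: {missing}")
    subjects, rejected = [], []
    for _, row in phen.iterrows():
        sid = row["subject"]
        ts_path = root / series[sid]
        try:
            ts = _read_series(ts_path, names)
        except (OSError, ValueError) as exc:
            rejected.append((sid, str(exc)))
            continue
        fd_rel = manifest.get("fd", {}).get(sid)
        if fd_rel is not None:
            fd = np.loadtxt(root / fd_rel, ndmin=1)
        else:
            fd = np.full(ts.shape[0], float(row.get("mean_fd", 0.0)))
            fd[0] = 0.0
        behaviors = {k: row[k] for k in phen.columns
                     if k not in ("subject", "site", "group", "age", "sex",
                                  "mean_fd", "tr", "eye_status",
                                  "latent_severity")}
        subjects.append(SubjectRecord(
            subject_id=sid, site=row["site"], group=row["group"],
            age=float(row["age"]), sex=row["sex"], tr=float(row["tr"]),
            eye_status=row.get("eye_status", "open"), timeseries=ts,
            fd_trace=fd,
            latent_severity=float(row.get("latent_severity", 0.0)),
            behaviors=behaviors))
    if rejected:
        warnings.warn(f"{len(rejected)} subject(s) rejected: "
                      f"{[sid for sid, _ in rejected]}", stacklevel=2)
    provenance = dict(manifest.get("provenance", {}),
                      manifest=str(mpath), rejected=rejected)
    cohort = CohortDataset(atlas=atlas, subjects=subjects,
                           provenance=provenance)
    profile = None
    if "profile_mean_conn" in manifest:
        mean_conn = pd.read_csv(root / manifest["profile_mean_conn"],
                                sep="\t", header=None).to_numpy(float)
        paths = pd.read_csv(root / manifest["profile_path_lengths"],
                            sep="\t")
        from scipy.spatial.distance import cdist
        cent = atlas.centroids
        profile = ReferenceProfile(mean_conn=mean_conn, path_lengths=paths,
                                   centroid_dist=cdist(cent, cent))
    return cohort, profile


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    """Bundle of every stage's outputs plus per-stage subject counts."""

    config: RunConfig
    included: list[str]
    excluded: list[str]
    phenotypes: pd.DataFrame
    features: FeatureTable
    glm_results: dict[str, pd.DataFrame]
    combined: pd.DataFrame
    selected: FeatureTable
    selected_results: pd.DataFrame
    residualized: pd.DataFrame
    method_averages: pd.DataFrame
    feature_corr: pd.DataFrame | None = None
    feature_graph: object | None = None
    behavior_corr: pd.DataFrame | None = None
    generalizability: object | None = None
    factor_partials: pd.DataFrame | None = None
    stage_log: dict = field(default_factory=dict)


def run_pipeline(cohort: CohortDataset, profile: ReferenceProfile,
                 config: RunConfig | None = None,
                 behaviors: pd.DataFrame | None = None) -> PipelineResult:
    """Execute the full analysis on an in-memory cohort."""
    cfg = config or RunConfig()
    stage_log: dict = {"n_input_subjects": len(cohort.subjects)}

    # --- QC: volume censoring and subject inclusion
    included, excluded = [], []
    pct_free = {}
    for s in cohort.subjects:
        mask = qc.censor_volumes(s.fd_trace, threshold=cfg.fd_threshold_mm)
        pct_free[s.subject_id] = mask.frac_kept
        (included if qc.include_subject(mask, cfg.min_frac_kept)
         else excluded).append(s.subject_id)
    kept_subjects = [s for s in cohort.subjects
                     if s.subject_id in set(included)]
    stage_log["n_after_qc"] = len(included)
    log.info("QC: %d/%d subjects retained", len(included),
             len(cohort.subjects))
    phen = cohort.phenotype_frame().set_index("subject").loc[included]
    phen["pct_motion_free"] = pd.Series(pct_free).loc[included]

    # --- connectivity + features
    extractor = ConnectivityFeatureExtractor(
        atlas=cohort.atlas, profile=profile, methods=cfg.methods,
        eval_lag_seconds=cfg.eval_lag_seconds,
        fd_threshold_mm=cfg.fd_threshold_mm,
        strength_lo=cfg.strength_lo, strength_hi=cfg.strength_hi,
        strength_width=cfg.strength_width, euclid_width=cfg.euclid_width,
        euclid_max=cfg.euclid_max, path_width=cfg.path_width,
        path_max=cfg.path_max,
        n_modularity_restarts=cfg.n_modularity_restarts,
        random_state=cfg.seed).fit()
    features = extractor.transform(kept_subjects)
    stage_log["n_features"] = features.values.shape[1]

    # --- group statistics: pooled and per site
    sites = sorted(phen["site"].unique())
    pooled_covs = tuple(c for c in cfg.covariates
                        if c != "site" or len(sites) > 1)
    glm_results = {}
    pooled_model = MassUnivariateGLM(covariates=pooled_covs,
                                     alpha=cfg.alpha, q_level=cfg.q_level)
    pooled_model.fit(features, phen)
    glm_results["pooled"] = pooled_model.results_
    site_covs = tuple(c for c in cfg.covariates if c != "site")
    for site in sites:
        site_phen = phen[phen["site"] == site]
        counts = site_phen["group"].value_counts()
        if len(counts) < 2 or counts.min() < 2:
            log.info("site %s skipped in per-site GLM", site)
            continue
        sub = FeatureTable(values=features.values.loc[site_phen.index],
                           definitions=features.definitions)
        glm_results[site] = MassUnivariateGLM(
            covariates=site_covs, alpha=cfg.alpha,
            q_level=cfg.q_level).fit(sub, site_phen).results_
    combined = combine_and_correct(
        list(glm_results.values()), list(glm_results), cfg.q_level)

    # --- selection and residualization (from the pooled comparison)
    selected = select_features(glm_results["pooled"], features, cfg.alpha)
    sel_ids = set(d.feature_id for d in selected.definitions)
    selected_results = glm_results["pooled"][
        glm_results["pooled"]["feature_id"].isin(sel_ids)]
    stage_log["n_selected"] = len(selected.definitions)
    resid_covs = tuple(c for c in ("site", "age", "sex", "motion")
                       if c != "site" or len(sites) > 1)
    if selected.definitions:
        from .groupstats import residualize
        residualized = residualize(selected, phen, nuisance=resid_covs)
    else:
        residualized = selected.values.copy()
    method_avgs = method_average(
        FeatureTable(values=residualized, definitions=selected.definitions)
        if selected.definitions else selected)

    result = PipelineResult(
        config=cfg, included=included, excluded=excluded, phenotypes=phen,
        features=features, glm_results=glm_results, combined=combined,
        selected=selected, selected_results=selected_results,
        residualized=residualized, method_averages=method_avgs,
        stage_log=stage_log)

    # --- cross-method analyses on the autism group
    autism_ids = phen.index[phen["group"] == "autism"]
    if len(selected.definitions) >= 2 and len(autism_ids) >= 3:
        resid_tab = FeatureTable(values=residualized,
                                 definitions=selected.definitions)
        corr, _ = feature_correlation_matrix(resid_tab,
                                             subjects=autism_ids)
        result.feature_corr = corr
        result.feature_graph = build_feature_graph(
            corr, cfg.graph_threshold, methods=selected.methods)
    behav_cols = [c for c in phen.columns
                  if c in ("VIQ", "PIQ", "FIQ") or c.startswith(
                      ("ADOS", "ADI", "SRS"))]
    if behaviors is None and behav_cols:
        behaviors = phen[behav_cols]
    if (behaviors is not None and len(method_avgs.columns)
            and len(autism_ids) >= 3):
        result.behavior_corr, _ = behavior_correlations(
            method_avgs.loc[autism_ids],
            behaviors.loc[[i for i in autism_ids
                           if i in behaviors.index]])

    # --- leave-one-site-out generalizability
    eligible = [s for s in sites
                if (phen[phen["site"] == s]["group"]
                    .value_counts().min() >= 2)
                and phen[phen["site"] == s]["group"].nunique() == 2]
    if len(eligible) >= 3 and len(selected.definitions) >= 3:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = site_generalizability(
                selected, phen,
                cohort=CohortDataset(
                    atlas=cohort.atlas, subjects=kept_subjects,
                    provenance=cohort.provenance),
                covariates=site_covs)
            result.generalizability = report
            result.factor_partials = factor_partial_correlations(report)

    if cfg.out_dir:
        _write_outputs(result, Path(cfg.out_dir))
    return result


def _config_hash(cfg: RunConfig) -> str:
    # hash the analysis parameters only, not input/output locations
    d = dataclasses.asdict(cfg)
    for key in ("cohort_dir", "atlas_path", "profile_path", "out_dir"):
        d.pop(key, None)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = _config_hash(result.config)
    for cohort_name, tab in result.glm_results.items():
        tab.assign(cohort=cohort_name, config=cfg_hash).to_csv(
            out / f"glm_{cohort_name}.csv", index=False)
    result.combined.assign(config=cfg_hash).to_csv(
        out / "glm_combined.csv", index=False)
    result.selected_results.assign(config=cfg_hash).to_csv(
        out / "selected_features.csv", index=False)
    result.selected.definitions_frame().to_csv(
        out / "feature_definitions.csv", index=False)
    result.method_averages.to_csv(out / "method_averages.csv")
    if result.feature_graph is not None:
        result.feature_graph.edge_frame().to_csv(
            out / "feature_graph_edges.csv", index=False)
        nodes = pd.DataFrame(
            [(n, d.get("method", "")) for n, d in
             result.feature_graph.graph.nodes(data=True)],
            columns=["feature_id", "method"])
        nodes.to_csv(out / "feature_graph_nodes.csv", index=False)
    if result.behavior_corr is not None:
        result.behavior_corr.to_csv(out / "behavior_correlations.csv")
    if result.generalizability is not None:
        result.generalizability.table.to_csv(out / "generalizability.csv")
        result.factor_partials.to_csv(out / "factor_partials.csv")
    manifest = dict(config=dataclasses.asdict(result.config),
                    config_hash=cfg_hash, stage_log=result.stage_log,
                    versions=dict(fcmethods=__version__,
                                  numpy=np.__version__,
                                  pandas=pd.__version__))
    manifest["config"]["covariates"] = list(
        manifest["config"]["covariates"])
    manifest["config"]["methods"] = list(manifest["config"]["methods"])
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
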