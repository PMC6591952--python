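"""End-to-end evaluation studies on synthetic cohorts.

These routines run the pipeline under controlled synthetic conditions
and summarize what it recovers: the structural constants of the
parcellation and bin schemes, type-I-error calibration on null
cohorts, planted-effect and behavior-coupling recovery, and the
dependence of leave-one-site-out generalizability on site size.  They
back both the validation test suite and the reproduction script.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from . import qc
from .atlas import make_distance_bins, make_strength_bins
from .connectivity import connectivity_matrix
from .crossmethod import factor_partial_correlations, site_generalizability
from .features import (ConnectivityFeatureExtractor, FeatureDefinition,
                       FeatureTable)
from .groupstats import MassUnivariateGLM, glm_group_difference
from .pipeline import RunConfig, run_pipeline
from .synth import (SyntheticSpec, family_target_pairs, generate_behaviors,
                    generate_cohort, generate_reference_profile,
                    make_synthetic_atlas, null_spec, salience_set_indices)


def _sub_seed(seed: int, offset: int) -> int:
    return int((seed * 1_000 + offset) % (2 ** 31 - 1))


def structural_constants(seed: int = 0) -> dict:
    """Constants of the full-size parcellation and its bin schemes."""
    spec = SyntheticSpec(n_regions=361, seed=_sub_seed(seed, 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        profile, atlas = generate_reference_profile(
            spec, n_reference_subjects=10, n_timepoints=150)
        strength = make_strength_bins(profile)
        path = make_distance_bins(profile, "path_length")
        euclid = make_distance_bins(profile, "euclidean_distance")
    comp = atlas.compartments
    hemi = atlas.hemispheres
    return dict(
        n_regions=atlas.n_regions,
        compartment_counts=atlas.counts,
        n_cortical_left=int(((comp == "cortical")
                             & (hemi == "left")).sum()),
        n_cortical_right=int(((comp == "cortical")
                              & (hemi == "right")).sum()),
        strength_bin_count=strength.bin_count,
        path_bins_retained=len(path.retained_bins),
        euclid_bins_retained=len(euclid.retained_bins),
        salience_set_size=len(salience_set_indices(atlas)),
        dmn_set_size=len(atlas.indices(network="default",
                                       compartment="cortical")),
    )


def _pair_feature_table(cohort) -> FeatureTable:
    """All region-pair connectivity values as a feature table."""
    r = cohort.atlas.n_regions
    iu = np.triu_indices(r, 1)
    rows, ids = [], []
    for s in cohort.subjects:
        mask = qc.censor_volumes(s.fd_trace)
        rows.append(connectivity_matrix(s.timeseries, mask).values[iu])
        ids.append(s.subject_id)
    values = pd.DataFrame(np.asarray(rows), index=ids)
    values.columns = [f"pair:{i}-{j}" for i, j in zip(*iu)]
    defs = [FeatureDefinition(c, "pair", c) for c in values.columns]
    return FeatureTable(values=values, definitions=defs)


def null_calibration(seed: int = 0, n_cohorts: int = 10) -> dict:
    """Type-I-error rate of the region-pair group GLM on null cohorts.

    Each cohort has zero planted effects (2 sites x 40 per group, the
    full 361-region scheme); the per-cohort fraction of pair tests
    with p < .05 is averaged over cohorts, since pair statistics
    within one cohort are positively dependent and a single cohort's
    fraction is a noisy estimate of the rate.
    """
    fracs, m = [], None
    for k in range(n_cohorts):
        spec = null_spec(n_sites=2, per_site_n=[(40, 40), (40, 40)],
                         n_regions=361, n_timepoints=150,
                         seed=_sub_seed(seed, 100 + k))
        cohort = generate_cohort(spec)
        table = _pair_feature_table(cohort)
        res = glm_group_difference(table, cohort.phenotype_frame())
        fracs.append(float((res["p"] < 0.05).mean()))
        m = len(res)
    return dict(mean_frac_p05=float(np.mean(fracs)),
                per_cohort_fracs=fracs, n_tests_per_cohort=m,
                binomial_3se=float(3 * np.sqrt(0.05 * 0.95 / m)))


def null_pipeline_fdr(seed: int = 0, n_runs: int = 20) -> dict:
    """Full-pipeline false-discovery behavior on small null cohorts."""
    clean = 0
    for k in range(n_runs):
        spec = null_spec(n_sites=2, per_site_n=[(15, 15), (15, 15)],
                         n_regions=45, n_timepoints=120,
                         seed=_sub_seed(seed, 300 + k))
        cohort = generate_cohort(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            profile, _ = generate_reference_profile(
                spec, n_reference_subjects=10, n_timepoints=120)
            result = run_pipeline(
                cohort, profile,
                RunConfig(n_modularity_restarts=2,
                          seed=_sub_seed(seed, 300 + k)))
        n_disc = int((result.glm_results["pooled"]["q"] < 0.05).sum())
        clean += n_disc == 0
    return dict(n_runs=n_runs, frac_runs_without_discoveries=clean / n_runs)


def homotopic_recovery(seed: int = 0, n_per_group: int = 100,
                       n_regions: int = 60) -> dict:
    """Recovery of an isolated planted homotopic deficit.

    The default homotopic effect (-0.08 in correlation units, about
    d = 0.8 against the between-subject sd of a pair correlation) is
    planted alone; the pipeline's homotopic features are tested with
    the standard covariates and the planted pairs are checked for
    selection at p < .05 with the planted (negative) sign.
    """
    effect_map = {k: 0.0 for k in SyntheticSpec().effect_map}
    effect_map["homotopic"] = -0.08
    half = n_per_group // 2
    spec = SyntheticSpec(
        n_sites=2, per_site_n=[(half, half),
                               (n_per_group - half, n_per_group - half)],
        n_regions=n_regions, n_timepoints=150, effect_map=effect_map,
        seed=_sub_seed(seed, 500))
    cohort = generate_cohort(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        profile, _ = generate_reference_profile(
            spec, n_reference_subjects=10, n_timepoints=150)
        extractor = ConnectivityFeatureExtractor(
            atlas=cohort.atlas, profile=profile, methods=("homotopic",),
            include_summary_means=False).fit()
        features = extractor.transform(cohort.subjects)
    res = MassUnivariateGLM().fit(
        features, cohort.phenotype_frame()).results_
    n_pairs = len(res)
    hit = ((res["p"] < 0.05) & (res["t"] < 0)).mean()
    sign_ok = (res["t"] < 0).mean()
    # planted group difference recovered on the correlation scale
    pairs = family_target_pairs(cohort.atlas)["homotopic"]
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    by_group = {"autism": [], "control": []}
    for s in cohort.subjects:
        mask = qc.censor_volumes(s.fd_trace)
        c = connectivity_matrix(s.timeseries, mask).values
        by_group[s.group].append(float(c[ii, jj].mean()))
    diff = float(np.mean(by_group["autism"])
                 - np.mean(by_group["control"]))
    return dict(n_planted_pairs=n_pairs,
                frac_selected_correct_sign=float(hit),
                frac_sign_correct=float(sign_ok),
                mean_group_difference=diff, planted_difference=-0.08)


def behavior_coupling_recovery(seed: int = 0, n_per_group: int = 200,
                               coupling: float = 0.3) -> dict:
    """Empirical correlation between behavior and the planted trait."""
    spec = SyntheticSpec(n_sites=1, per_site_n=[(n_per_group,
                                                 n_per_group)],
                         n_regions=45, n_timepoints=60,
                         behavior_coupling=coupling,
                         seed=_sub_seed(seed, 700))
    cohort = generate_cohort(spec)
    behav = generate_behaviors(cohort, spec)
    sev = pd.Series({s.subject_id: s.latent_severity
                     for s in cohort.subjects})
    scores = behav["SRS_total"]
    ok = scores.notna()
    r = float(np.corrcoef(scores[ok], sev[ok])[0, 1])
    return dict(planted_coupling=coupling, recovered_coupling=r,
                abs_error=abs(r - coupling), n_observed=int(ok.sum()))


def censoring_group_gap(seed: int = 0, n_per_group: int = 200) -> dict:
    """Percent of volumes censored per group under the 0.3 mm rule."""
    spec = null_spec(n_sites=1, per_site_n=[(n_per_group, n_per_group)],
                     n_regions=45, n_timepoints=150,
                     seed=_sub_seed(seed, 800))
    cohort = generate_cohort(spec)
    summary, t, p = qc.percent_censored_by_group(cohort)
    return dict(
        pct_censored_autism=100 * summary["autism"][0],
        pct_censored_control=100 * summary["control"][0],
        t=t, p=p)


GENERALIZABILITY_SITE_NS = (10, 15, 25, 40, 60)


def generalizability_study(seed: int = 0, n_reps: int = 20,
                           n_regions: int = 45) -> dict:
    """Partial correlation of r_gen with site factors when only the
    number of subjects per site varies.

    All sites share TR, series length, eye status and generative
    effects; only per-site n differs.  Reports the mean partial
    correlation per factor over replicates and how often the
    subjects-per-site factor ranks first.
    """
    partials = []
    top_count = 0
    for k in range(n_reps):
        spec = SyntheticSpec(
            n_sites=len(GENERALIZABILITY_SITE_NS),
            per_site_n=[(n, n) for n in GENERALIZABILITY_SITE_NS],
            n_regions=n_regions, n_timepoints=120, tr_seconds=2.0,
            eye_status=["open"] * len(GENERALIZABILITY_SITE_NS),
            seed=_sub_seed(seed, 900 + k))
        cohort = generate_cohort(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            profile, _ = generate_reference_profile(
                spec, n_reference_subjects=8, n_timepoints=120)
            extractor = ConnectivityFeatureExtractor(
                atlas=cohort.atlas, profile=profile,
                methods=("strength_bin", "euclid_bin", "homotopic",
                         "thalamocortical", "corticostriatal",
                         "dmn_within", "salience_within")).fit()
            features = extractor.transform(cohort.subjects)
            report = site_generalizability(
                features, cohort.phenotype_frame(), cohort=cohort)
            pr = factor_partial_correlations(report)["partial_r"]
        partials.append(pr)
        finite = pr.dropna()
        top_count += int(finite.idxmax() == "n_subjects"
                         and finite.max() > 0)
    mean_partials = pd.concat(partials, axis=1).mean(axis=1)
    return dict(mean_partial_r=mean_partials.to_dict(),
                n_subjects_mean_partial_r=float(
                    mean_partials["n_subjects"]),
                frac_reps_n_subjects_top=top_count / n_reps,
                n_reps=n_reps)


def run_all(seed: int = 0, scale: float = 1.0) -> dict:
    """Every evaluation study with one master seed."""
    return dict(
        structural=structural_constants(seed),
        calibration=null_calibration(seed),
        pipeline_fdr=null_pipeline_fdr(seed),
        recovery=homotopic_recovery(seed),
        behavior=behavior_coupling_recovery(seed),
        censoring=censoring_group_gap(seed),
        generalizability=generalizability_study(seed),
    )
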