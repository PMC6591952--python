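"""Synthetic multi-site cohort generator with known planted structure.

Emulates the inputs of a multi-site resting-state study — per-subject
ROI time series, phenotypes (site, group, age, sex, motion, eye status,
TR), a normative reference cohort, and behavior scores — so that every
downstream stage of the pipeline has a recoverable ground truth.

The generative model: each subject has a target correlation matrix
built from a latent block (network) structure, a site intercept, and
group effects planted on targeted region-pair families (homotopic
pairs, thalamic and striatal seed maps, within-network pairs, or all
pairs); the matrix is projected to the nearest correlation matrix and
the ROI series are drawn as a first-order autoregressive process whose
stationary cross-sectional covariance equals that target.  Empirical
connectivity differences therefore match the planted effects up to
sampling error.  Head motion is drawn per group (framewise
displacement ~ exponential around the group mean), which reproduces a
realistic censored-volume gap between groups under the 0.3 mm rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .atlas import (Region, RegionAtlas, build_atlas, find_homotopic_pairs,
                    make_distance_bins)

SUBCORTICAL_NAMES = ("thalamus", "caudate", "putamen", "pallidum",
                     "accumbens", "amygdala", "hippocampus")
STRIATAL_SEEDS = ("caudate", "putamen", "pallidum", "accumbens")
CEREBELLAR_NETWORKS = ("visual", "somatomotor", "dorsal_attention",
                       "ventral_attention", "limbic", "frontoparietal",
                       "default")
#: cortical network label counts of the reference parcellation
NETWORK_COUNTS = {"default": 41, "salience": 4, "dorsal_attention": 32}
#: labels forming the combined salience/dorsal-attention feature set
SALIENCE_SET_LABELS = ("salience", "dorsal_attention")

DEFAULT_EFFECT_MAP = {
    "homotopic": -0.08,
    "thalamocortical": -0.05,
    "corticostriatal": -0.05,
    "dmn": -0.05,
    "salience": -0.04,
    "global": -0.02,
    "lag": -0.05,          # shift of the AR(1) coefficient, not a correlation
}

DEFAULT_MOTION_PARAMS = {"autism": (0.11, 0.05), "control": (0.10, 0.05)}


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic multi-site cohort."""

    n_sites: int = 4
    per_site_n: list[tuple[int, int]] | None = None   # (autism, control)
    n_regions: int = 361
    n_timepoints: list[int] | int | None = None       # per site
    tr_seconds: list[float] | float | None = None     # per site
    eye_status: list[str] | None = None               # per site
    effect_map: dict = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_MAP))
    motion_params: dict = field(
        default_factory=lambda: dict(DEFAULT_MOTION_PARAMS))
    behavior_coupling: float = 0.3
    behavior_missingness: float = 0.3
    base_connectivity: dict = field(default_factory=lambda: {
        "within": 0.35, "between_mean": 0.05, "between_sd": 0.07,
        "pair_sd": 0.02})
    site_sd: float = 0.02
    ar_coef: float = 0.4
    severity_sd: float = 0.3
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be positive")
        if self.n_regions < 40:
            raise ValueError("n_regions must be >= 40 (the atlas needs "
                             "subcortical seeds and network sets)")
        if self.per_site_n is not None:
            for n_a, n_c in self.per_site_n:
                if n_a < 1 or n_c < 1:
                    raise ValueError("per-site group counts must be positive")
        if not -1.0 <= self.behavior_coupling <= 1.0:
            raise ValueError("behavior_coupling must lie in [-1, 1]")
        # coarse bound on implied correlations before any simulation
        conn_deltas = [abs(v) for k, v in self.effect_map.items()
                       if k != "lag"]
        bound = (self.base_connectivity["within"]
                 + 2.0 * sum(conn_deltas))
        if bound >= 1.0:
            raise ValueError(
                f"effect_map implies correlations with |r| >= 1 "
                f"(bound {bound:.2f}); reduce the planted effects")


@dataclass
class SubjectRecord:
    """One participant: ROI time series plus phenotype covariates."""

    subject_id: str
    site: str
    group: str                       # "autism" | "control"
    age: float
    sex: str                         # "M" | "F"
    tr: float
    eye_status: str                  # "open" | "closed"
    timeseries: np.ndarray           # (T, R)
    fd_trace: np.ndarray             # (T,)
    latent_severity: float = 0.0     # planted subject-level effect magnitude
    behaviors: dict = field(default_factory=dict)

    @property
    def mean_fd(self) -> float:
        return float(np.mean(self.fd_trace))

    @property
    def n_volumes(self) -> int:
        return self.timeseries.shape[0]


@dataclass
class CohortDataset:
    """An atlas plus subject records, with generation provenance."""

    atlas: RegionAtlas
    subjects: list[SubjectRecord]
    provenance: dict = field(default_factory=dict)

    @property
    def sites(self) -> list[str]:
        return sorted({s.site for s in self.subjects})

    def phenotype_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = dict(subject=s.subject_id, site=s.site, group=s.group,
                       age=s.age, sex=s.sex, mean_fd=s.mean_fd, tr=s.tr,
                       eye_status=s.eye_status,
                       latent_severity=s.latent_severity)
            row.update(s.behaviors)
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic atlas geometry
# ---------------------------------------------------------------------------

# hemisphere box (left side); sized so the maximum pairwise centroid
# distance stays below 165 mm while the x gap keeps all pairs above 5 mm
_XL, _XH = -72.0, -8.0
_YL, _YH = -55.0, 5.0
_ZL, _ZH = -25.0, 25.0
# far-corner anchors guaranteeing occupancy of the longest 5-mm strata
_ANCHORS = [(-72.0, -55.0, -25.0), (-72.0, -55.0, 25.0)]
_ANCHOR_CHAIN = [(-72.0, -55.0 + s, 24.0) for s in (12, 22, 32, 42, 52, 60)]


def _atlas_layout(n_regions: int) -> dict:
    """Compartment layout scaled from the 361-region scheme."""
    if n_regions == 361:
        return dict(n_cort_pairs=161, n_cort_extra_right=11,
                    n_sub_pairs=7, n_cereb_pairs=7,
                    network_counts=dict(NETWORK_COUNTS))
    n_sub_pairs = 7
    n_cereb_pairs = 7 if n_regions >= 80 else 2
    n_cort = n_regions - 2 * (n_sub_pairs + n_cereb_pairs)
    n_extra = int(round(n_cort * 11 / 333))
    n_pairs = (n_cort - n_extra) // 2
    n_extra = n_cort - 2 * n_pairs
    frac = n_cort / 333
    counts = {
        "default": max(4, int(round(41 * frac))),
        "salience": max(2, int(round(4 * frac))),
        "dorsal_attention": max(3, int(round(32 * frac))),
    }
    if sum(counts.values()) > n_cort:
        raise ValueError(f"n_regions={n_regions} too small for network sets")
    return dict(n_cort_pairs=n_pairs, n_cort_extra_right=n_extra,
                n_sub_pairs=n_sub_pairs, n_cereb_pairs=n_cereb_pairs,
                network_counts=counts)


def _sample_points(rng, n: int, box: tuple, existing: list,
                   min_sep: float) -> list:
    lo = np.array([box[0], box[2], box[4]])
    hi = np.array([box[1], box[3], box[5]])
    pts = list(existing)
    out = []
    for _ in range(n):
        for _attempt in range(4000):
            cand = lo + rng.random(3) * (hi - lo)
            if not pts or np.min(cdist([cand], np.asarray(pts))) >= min_sep:
                pts.append(cand)
                out.append(cand)
                break
        else:
            raise RuntimeError("could not place centroid with the required "
                               "separation; box too crowded")
    return out


def make_synthetic_atlas(n_regions: int = 361, seed: int | None = 0,
                         rng: np.random.Generator | None = None,
                         jitter: float = 0.4, min_sep: float = 6.2,
                         ensure_distance_strata: bool | None = None,
                         max_tries: int = 40) -> RegionAtlas:
    """Mirror-symmetric synthetic parcellation with compliant geometry.

    Left-hemisphere centroids are sampled (with a minimum mutual
    separation, in a box bounding all pairwise distances by ~164 mm);
    right-hemisphere centroids are their mirror images plus sub-mm
    jitter, so mutual-nearest homotopic pairing recovers the planted
    pairs exactly.  Unpaired extra right-cortical regions make the
    hemispheric counts asymmetric as in real parcellations.  For
    full-size atlases the pairwise-distance histogram is checked to
    occupy every 5-mm stratum above 5 mm (resampling a bounded number
    of times if needed) so that the Euclidean bin scheme retains its
    full complement of bins.
    """
    layout = _atlas_layout(n_regions)
    if ensure_distance_strata is None:
        ensure_distance_strata = n_regions >= 300
    base_rng = rng if rng is not None else np.random.default_rng(seed)
    for _try in range(max_tries):
        atlas = _build_synthetic_atlas_once(layout, base_rng, jitter, min_sep)
        if not ensure_distance_strata:
            return atlas
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scheme = make_distance_bins(atlas, "euclidean_distance")
        # first 5-mm bin must be empty, every later in-range stratum full
        if scheme.dropped_bins == [0]:
            return atlas
    raise RuntimeError("failed to generate strata-compliant centroids")


def _build_synthetic_atlas_once(layout, rng, jitter, min_sep):
    n_pairs = layout["n_cort_pairs"]
    anchors = [np.array(a) for a in _ANCHORS + _ANCHOR_CHAIN]
    anchors = anchors[:n_pairs]
    cort_box = (_XL, _XH, _YL, _YH, _ZL, _ZH)
    sub_box = (-30.0, -9.0, -30.0, 0.0, -15.0, 15.0)
    cereb_box = (-45.0, -9.0, -55.0, -30.0, -25.0, -5.0)
    left_cort = anchors + _sample_points(
        rng, n_pairs - len(anchors), cort_box, anchors, min_sep)
    accepted = list(left_cort)
    extra = _sample_points(rng, layout["n_cort_extra_right"], cort_box,
                           accepted, min_sep)
    accepted += extra
    sub = _sample_points(rng, layout["n_sub_pairs"], sub_box, accepted,
                         min_sep)
    accepted += sub
    cereb = _sample_points(rng, layout["n_cereb_pairs"], cereb_box, accepted,
                           min_sep)

    def mirrored(p):
        j = rng.uniform(-jitter, jitter, size=3)
        return (-p[0] + j[0], p[1] + j[1], p[2] + j[2])

    records = []
    rid = 0

    def add(name, hemi, comp, net, cent):
        nonlocal rid
        records.append(dict(id=rid, name=name, hemisphere=hemi,
                            compartment=comp, network=net or "",
                            x=cent[0], y=cent[1], z=cent[2]))
        rid += 1

    # cortical pairs then extras; network labels assigned afterwards
    for i, p in enumerate(left_cort):
        add(f"ctx_{i + 1:03d}_L", "left", "cortical", "", tuple(p))
        add(f"ctx_{i + 1:03d}_R", "right", "cortical", "", mirrored(p))
    for i, p in enumerate(extra):
        add(f"ctx_extra_{i + 1:02d}_R", "right", "cortical", "", mirrored(p))
    for i, p in enumerate(sub):
        name = SUBCORTICAL_NAMES[i % len(SUBCORTICAL_NAMES)]
        suffix = "" if i < len(SUBCORTICAL_NAMES) else f"_{i // 7 + 1}"
        add(f"{name}{suffix}_L", "left", "subcortical", "", tuple(p))
        add(f"{name}{suffix}_R", "right", "subcortical", "", mirrored(p))
    for i, p in enumerate(cereb):
        net = CEREBELLAR_NETWORKS[i % len(CEREBELLAR_NETWORKS)]
        add(f"cereb_{net}_L", "left", "cerebellar", f"cereb_{net}", tuple(p))
        add(f"cereb_{net}_R", "right", "cerebellar", f"cereb_{net}",
            mirrored(p))
    # plant cortical network labels in region order
    cortical_idx = [i for i, r in enumerate(records)
                    if r["compartment"] == "cortical"]
    pos = 0
    for label, count in layout["network_counts"].items():
        for _ in range(count):
            records[cortical_idx[pos]]["network"] = label
            pos += 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_atlas(records)


# ---------------------------------------------------------------------------
# planted-effect targets
# ---------------------------------------------------------------------------

def seed_indices(atlas: RegionAtlas, seed_name: str,
                 hemisphere: str) -> int:
    """Index of a named subcortical seed in the given hemisphere."""
    hemi_tag = {"left": "_l", "right": "_r"}[hemisphere]
    for i, r in enumerate(atlas.regions):
        if (r.compartment == "subcortical"
                and seed_name.lower() in r.name.lower()
                and r.name.lower().endswith(hemi_tag)):
            return i
    raise KeyError(f"no subcortical seed {seed_name!r} ({hemisphere})")


def salience_set_indices(atlas: RegionAtlas) -> np.ndarray:
    """Cortical members of the combined salience/dorsal-attention set."""
    nets = atlas.networks
    mask = np.isin(nets, SALIENCE_SET_LABELS)
    mask &= atlas.compartments == "cortical"
    return np.flatnonzero(mask)


def family_target_pairs(atlas: RegionAtlas) -> dict[str, list]:
    """Region-pair index sets targeted by each planted effect family."""
    targets: dict[str, list] = {}
    pairing = find_homotopic_pairs(atlas)
    targets["homotopic"] = list(pairing.pairs)
    comp = atlas.compartments
    hemi = atlas.hemispheres
    cortical = {h: np.flatnonzero((comp == "cortical") & (hemi == h))
                for h in ("left", "right")}
    for fam, seeds in (("thalamocortical", ("thalamus",)),
                       ("corticostriatal", STRIATAL_SEEDS)):
        pairs = []
        for sname in seeds:
            for h in ("left", "right"):
                try:
                    si = seed_indices(atlas, sname, h)
                except KeyError:
                    continue
                pairs += [(si, int(c)) for c in cortical[h]]
        targets[fam] = pairs
    dmn = np.flatnonzero((atlas.networks == "default")
                         & (comp == "cortical"))
    targets["dmn"] = [(int(a), int(b)) for ai, a in enumerate(dmn)
                      for b in dmn[ai + 1:]]
    sal = salience_set_indices(atlas)
    targets["salience"] = [(int(a), int(b)) for ai, a in enumerate(sal)
                           for b in sal[ai + 1:]]
    return targets


# ---------------------------------------------------------------------------
# correlation-model construction
# ---------------------------------------------------------------------------

def _block_ids(atlas: RegionAtlas) -> np.ndarray:
    labels = []
    for r in atlas.regions:
        if r.network:
            labels.append(r.network)
        elif r.compartment == "subcortical":
            labels.append("subcortical")
        else:
            labels.append(f"other_{r.region_id % 3}")
    uniq = {lab: i for i, lab in enumerate(sorted(set(labels)))}
    return np.array([uniq[lab] for lab in labels])


def base_correlation(atlas: RegionAtlas, base: dict,
                     rng: np.random.Generator) -> np.ndarray:
    """Block-structured latent correlation target (before effects)."""
    blocks = _block_ids(atlas)
    n_blocks = blocks.max() + 1
    between = rng.normal(base["between_mean"], base["between_sd"],
                         size=(n_blocks, n_blocks))
    between = np.clip((between + between.T) / 2, -0.12, 0.25)
    sigma = between[np.ix_(blocks, blocks)]
    sigma[blocks[:, None] == blocks[None, :]] = base["within"]
    noise = rng.normal(0.0, base["pair_sd"], size=sigma.shape)
    sigma = sigma + (noise + noise.T) / 2
    np.fill_diagonal(sigma, 1.0)
    return sigma


def nearest_correlation(sigma: np.ndarray,
                        eig_floor: float = 1e-3) -> np.ndarray:
    """Project a symmetric matrix to a positive-definite correlation."""
    sym = (sigma + sigma.T) / 2
    w, v = np.linalg.eigh(sym)
    w = np.maximum(w, eig_floor)
    out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def _simulate_series(chol: np.ndarray, phi: float, n_t: int,
                     noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """AR(1) series whose stationary covariance is chol @ chol.T."""
    n_reg = chol.shape[0]
    innov = rng.standard_normal((n_t, n_reg)) @ chol.T
    x = np.empty((n_t, n_reg))
    x[0] = innov[0]
    scale = np.sqrt(1.0 - phi ** 2)
    for t in range(1, n_t):
        x[t] = phi * x[t - 1] + scale * innov[t]
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(x.shape)
    return x


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _site_parameters(spec: SyntheticSpec, rng: np.random.Generator):
    tr_choices = (2.0, 1.5, 2.5, 3.0)
    sites = []
    for i in range(spec.n_sites):
        if spec.per_site_n is not None:
            n_a, n_c = spec.per_site_n[i]
        else:
            n_a = int(rng.integers(10, 121))
            n_c = int(rng.integers(10, 121))
        if isinstance(spec.tr_seconds, (int, float)):
            tr = float(spec.tr_seconds)
        elif spec.tr_seconds is not None:
            tr = float(spec.tr_seconds[i])
        else:
            tr = tr_choices[i % len(tr_choices)]
        if isinstance(spec.n_timepoints, int):
            n_t = spec.n_timepoints
        elif spec.n_timepoints is not None:
            n_t = int(spec.n_timepoints[i])
        else:
            n_t = int(rng.integers(120, 241))
        if spec.eye_status is not None:
            eye = spec.eye_status[i]
        else:
            eye = "open" if rng.random() < 0.7 else "closed"
        sites.append(dict(name=f"site_{i + 1:02d}", n_autism=n_a,
                          n_control=n_c, tr=tr, n_timepoints=n_t, eye=eye,
                          offset=float(rng.normal(0.0, spec.site_sd))))
    return sites


def generate_cohort(spec: SyntheticSpec) -> CohortDataset:
    """Simulate a full multi-site cohort from the planted model."""
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    ss_atlas, ss_base, ss_sites, ss_subjects = root.spawn(4)
    atlas = make_synthetic_atlas(spec.n_regions,
                                 rng=np.random.default_rng(ss_atlas))
    sigma0 = base_correlation(atlas, spec.base_connectivity,
                              np.random.default_rng(ss_base))
    targets = family_target_pairs(atlas)
    site_rng = np.random.default_rng(ss_sites)
    sites = _site_parameters(spec, site_rng)
    off_diag = ~np.eye(atlas.n_regions, dtype=bool)

    subjects = []
    subj_rng = np.random.default_rng(ss_subjects)
    counter = 0
    for site in sites:
        for group, n_grp in (("autism", site["n_autism"]),
                             ("control", site["n_control"])):
            for _ in range(n_grp):
                counter += 1
                sid = f"sub_{counter:04d}"
                severity = float(subj_rng.standard_normal())
                a_s = ((1.0 + spec.severity_sd * severity)
                       if group == "autism" else 0.0)
                sigma = sigma0.copy()
                sigma[off_diag] += site["offset"]
                for fam, delta in spec.effect_map.items():
                    if fam in ("lag",) or delta == 0.0:
                        continue
                    if fam == "global":
                        sigma[off_diag] += delta * a_s
                        continue
                    for (i, j) in targets.get(fam, ()):
                        sigma[i, j] += delta * a_s
                        sigma[j, i] += delta * a_s
                sigma = np.clip(sigma, -0.95, 0.95)
                np.fill_diagonal(sigma, 1.0)
                corr = nearest_correlation(sigma)
                chol = np.linalg.cholesky(corr)
                phi = spec.ar_coef + spec.effect_map.get("lag", 0.0) * a_s
                phi = float(np.clip(phi, 0.0, 0.95))
                ts = _simulate_series(chol, phi, site["n_timepoints"],
                                      spec.noise_sd, subj_rng)
                mu, sd = spec.motion_params[group]
                mean_fd = max(0.03, float(subj_rng.normal(mu, sd)))
                fd = subj_rng.exponential(mean_fd, site["n_timepoints"])
                fd[0] = 0.0
                age = float(np.clip(subj_rng.normal(15.0, 6.0), 6.0, 50.0))
                sex = "M" if subj_rng.random() < 0.8 else "F"
                subjects.append(SubjectRecord(
                    subject_id=sid, site=site["name"], group=group,
                    age=age, sex=sex, tr=site["tr"],
                    eye_status=site["eye"], timeseries=ts, fd_trace=fd,
                    latent_severity=a_s))
    provenance = dict(kind="synthetic", seed=spec.seed,
                      n_sites=spec.n_sites, n_regions=spec.n_regions,
                      effect_map=dict(spec.effect_map))
    return CohortDataset(atlas=atlas, subjects=subjects,
                         provenance=provenance)


# ---------------------------------------------------------------------------
# normative reference profile
# ---------------------------------------------------------------------------

def generate_reference_profile(spec: SyntheticSpec,
                               n_reference_subjects: int = 100,
                               n_timepoints: int = 200,
                               max_tries: int = 40):
    """Simulate a normative cohort and average its connectivity.

    Uses the same atlas and block model as :func:`generate_cohort`
    (identical seed substreams) with zero planted effects, then returns
    a :class:`~fcmethods.features.ReferenceProfile` holding the
    elementwise mean connectivity, centroid distances, and a synthetic
    structural path-length table (Euclidean distance times a
    tortuosity-like positive detour, so path length always dominates
    straight-line distance).
    """
    from .features import ReferenceProfile

    spec.validate()
    if n_reference_subjects < 2:
        raise ValueError("need at least 2 reference subjects")
    root = np.random.SeedSequence(spec.seed)
    ss_atlas, ss_base, _, _ = root.spawn(4)
    ss_ref, ss_paths = root.spawn(2)[0].spawn(2)
    atlas = make_synthetic_atlas(spec.n_regions,
                                 rng=np.random.default_rng(ss_atlas))
    sigma0 = base_correlation(atlas, spec.base_connectivity,
                              np.random.default_rng(ss_base))
    corr0 = nearest_correlation(sigma0)
    chol = np.linalg.cholesky(corr0)
    rng = np.random.default_rng(ss_ref)
    acc = np.zeros_like(corr0)
    for _ in range(n_reference_subjects):
        ts = _simulate_series(chol, spec.ar_coef, n_timepoints,
                              spec.noise_sd, rng)
        acc += np.corrcoef(ts, rowvar=False)
    mean_conn = acc / n_reference_subjects
    mean_conn = (mean_conn + mean_conn.T) / 2
    np.fill_diagonal(mean_conn, 1.0)

    cent = atlas.centroids
    centroid_dist = cdist(cent, cent)
    path_rng = np.random.default_rng(ss_paths)
    paths = _synthetic_path_lengths(atlas, centroid_dist, path_rng,
                                    max_tries=max_tries,
                                    validate=spec.n_regions >= 300)
    return ReferenceProfile(mean_conn=mean_conn, path_lengths=paths,
                            centroid_dist=centroid_dist), atlas


def _synthetic_path_lengths(atlas, centroid_dist, rng, max_tries=40,
                            validate=True) -> pd.DataFrame:
    iu = np.triu_indices(atlas.n_regions, k=1)
    d = centroid_dist[iu]
    for _ in range(max_tries):
        connected = rng.random(d.size) < np.exp(-d / 120.0)
        lengths = 1.1 * d[connected] + rng.exponential(100.0,
                                                       connected.sum())
        if not validate:
            break
        in_range = lengths[lengths <= 500.0]
        counts, _ = np.histogram(in_range, bins=10, range=(0.0, 500.0))
        if np.all(counts > 0):
            break
    else:
        raise RuntimeError("failed to generate a path-length table "
                           "occupying all 50-mm strata")
    return pd.DataFrame({
        "region_a": iu[0][connected],
        "region_b": iu[1][connected],
        "length_mm": lengths,
    })


# ---------------------------------------------------------------------------
# behavior scores
# ---------------------------------------------------------------------------

#: (mean, sd, sign of coupling to severity, autism-only?)
BEHAVIOR_DEFS = {
    "VIQ": (105.0, 15.0, -1.0, False),
    "PIQ": (105.0, 15.0, -1.0, False),
    "FIQ": (105.0, 15.0, -1.0, False),
    "ADOS_total": (11.0, 4.0, +1.0, True),
    "ADOS_social_affect": (8.0, 3.0, +1.0, True),
    "ADOS_rrb": (3.0, 1.5, +1.0, True),
    "ADI_social": (19.0, 5.0, +1.0, True),
    "ADI_verbal": (15.0, 4.0, +1.0, True),
    "ADI_rrb": (6.0, 2.0, +1.0, True),
    "ADI_onset": (3.0, 1.0, +1.0, True),
    "SRS_total": (70.0, 25.0, +1.0, False),
}


def generate_behaviors(cohort: CohortDataset, spec: SyntheticSpec,
                       coupling: float | None = None,
                       missingness: float | None = None) -> pd.DataFrame:
    """Behavior scores coupled to the planted subject-level effect.

    Each score is an affine function of the standardized latent effect
    magnitude plus independent noise at the requested coupling; a
    missingness mask emulates incompletely reported phenotypes.
    Diagnostic instruments (ADOS/ADI) are only observed in the autism
    group.  Scores are also stored on each subject record.
    """
    c = spec.behavior_coupling if coupling is None else coupling
    miss = (spec.behavior_missingness if missingness is None
            else missingness)
    if not -1.0 <= c <= 1.0:
        raise ValueError("coupling must lie in [-1, 1]")
    sev = np.array([s.latent_severity for s in cohort.subjects])
    sd = sev.std()
    z = (sev - sev.mean()) / sd if sd > 0 else np.zeros_like(sev)
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, 2_000_003]))
    n = len(cohort.subjects)
    table = {"subject": [s.subject_id for s in cohort.subjects]}
    autism = np.array([s.group == "autism" for s in cohort.subjects])
    for name, (mu, scale, sign, autism_only) in BEHAVIOR_DEFS.items():
        noise = rng.standard_normal(n)
        score = mu + scale * sign * (c * z + np.sqrt(1 - c ** 2) * noise)
        observed = rng.random(n) >= miss
        if autism_only:
            observed &= autism
        score = np.where(observed, score, np.nan)
        table[name] = score
    df = pd.DataFrame(table).set_index("subject")
    for subj in cohort.subjects:
        subj.behaviors = {
            k: (float(v) if np.isfinite(v) else np.nan)
            for k, v in df.loc[subj.subject_id].items()
        }
    return df


def null_spec(**overrides) -> SyntheticSpec:
    """A spec with every planted effect zeroed (null calibration)."""
    effect_map = {k: 0.0 for k in DEFAULT_EFFECT_MAP}
    base = SyntheticSpec(effect_map=effect_map)
    return replace(base, **overrides)
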