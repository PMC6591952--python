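"""Eight families of connectivity features from a subject's matrix.

Families: normative-strength bins, structural path-length bins,
Euclidean-distance bins, homotopic pairs, corticostriatal and
thalamocortical seed maps, within/between network pairs (default mode
and the combined salience/dorsal-attention set), idiosyncrasy (squared
deviation from the normative profile), graph segregation/integration
(modularity, global efficiency), and lagged connectivity.

:class:`ConnectivityFeatureExtractor` packages the families as a
scikit-learn transformer: ``fit`` derives the bin schemes, homotopic
pairing and pair index sets from the atlas and normative reference
profile; ``transform`` maps subject records to a
:class:`FeatureTable`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path
from sklearn.base import BaseEstimator, TransformerMixin

from . import qc
from .atlas import (BinScheme, HomotopicPairing, RegionAtlas,
                    find_homotopic_pairs, make_distance_bins,
                    make_strength_bins, upper_triangle)
from .connectivity import ConnectivityMatrix, connectivity_matrix, \
    lag_matrices, required_length
from .synth import SALIENCE_SET_LABELS, STRIATAL_SEEDS, seed_indices

#: families producing a single scalar per subject (excluded from the
#: per-feature selection pool by rule)
SCALAR_METHODS = ("idiosyncrasy", "modularity", "global_efficiency")

ALL_METHODS = ("strength_bin", "path_bin", "euclid_bin", "homotopic",
               "corticostriatal", "thalamocortical", "dmn_within",
               "salience_within", "dmn_salience_between",
               "idiosyncrasy", "modularity", "global_efficiency", "lag")


@dataclass
class ReferenceProfile:
    """Normative mean connectivity plus structural geometry.

    ``mean_conn`` is the across-participant mean region-pair
    connectivity of a reference cohort; ``path_lengths`` tabulates
    structurally connected pairs (columns region_a, region_b,
    length_mm); ``centroid_dist`` is the full Euclidean distance
    matrix between region centroids.
    """

    mean_conn: np.ndarray
    path_lengths: pd.DataFrame
    centroid_dist: np.ndarray

    def __post_init__(self):
        self.mean_conn = np.asarray(self.mean_conn, dtype=float)
        self.centroid_dist = np.asarray(self.centroid_dist, dtype=float)
        m = self.mean_conn
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("mean_conn must be square")
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValueError("mean_conn must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("mean_conn diagonal must be 1")
        d = self.centroid_dist
        if np.any(d < 0) or not np.allclose(d, d.T, atol=1e-8):
            raise ValueError("centroid_dist must be symmetric, non-negative")
        self.path_lengths = pd.DataFrame(self.path_lengths)

    @property
    def r(self) -> int:
        return self.mean_conn.shape[0]


@dataclass(frozen=True)
class FeatureDefinition:
    feature_id: str
    method: str
    anchor: str


@dataclass
class FeatureTable:
    """Subjects x features values with per-feature method tags."""

    values: pd.DataFrame
    definitions: list[FeatureDefinition]

    def __post_init__(self):
        ids = [d.feature_id for d in self.definitions]
        if list(self.values.columns) != ids:
            raise ValueError("column order must match definitions")

    @property
    def methods(self) -> pd.Series:
        return pd.Series({d.feature_id: d.method for d in self.definitions})

    def subset(self, feature_ids) -> "FeatureTable":
        keep = set(feature_ids)
        defs = [d for d in self.definitions if d.feature_id in keep]
        return FeatureTable(
            values=self.values[[d.feature_id for d in defs]].copy(),
            definitions=defs)

    def definitions_frame(self) -> pd.DataFrame:
        return pd.DataFrame([d.__dict__ for d in self.definitions])


# ---------------------------------------------------------------------------
# per-family operations
# ---------------------------------------------------------------------------

def _pairs_in_bins(scheme: BinScheme, values: np.ndarray,
                   iu: tuple) -> dict[int, tuple]:
    """Upper-triangle pair index arrays per retained bin."""
    idx = scheme.assign(values)
    out = {}
    for b in scheme.retained_bins:
        member = idx == b
        if not member.any():
            raise RuntimeError(
                f"retained bin {b} has no members on this reference")
        out[b] = (iu[0][member], iu[1][member])
    return out


def _bin_means(conn_values: np.ndarray, bin_pairs: dict) -> pd.Series:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return pd.Series({b: float(np.nanmean(conn_values[rows, cols]))
                          for b, (rows, cols) in bin_pairs.items()})


def strength_bin_features(conn: ConnectivityMatrix,
                          profile: ReferenceProfile,
                          scheme: BinScheme) -> pd.Series:
    """Mean subject connectivity per normative-strength bin."""
    if conn.r != profile.r:
        raise ValueError("conn and profile region counts differ")
    iu = np.triu_indices(profile.r, k=1)
    bin_pairs = _pairs_in_bins(scheme, profile.mean_conn[iu], iu)
    return _bin_means(conn.values, bin_pairs)


def distance_bin_features(conn: ConnectivityMatrix,
                          profile: ReferenceProfile,
                          scheme: BinScheme) -> pd.Series:
    """Mean subject connectivity per distance stratum.

    Euclidean schemes use all region pairs; path-length schemes use
    only the structurally connected pairs of the reference table.
    """
    if scheme.kind == "euclidean_distance":
        iu = np.triu_indices(profile.r, k=1)
        values = profile.centroid_dist[iu]
    elif scheme.kind == "path_length":
        tab = profile.path_lengths
        iu = (tab["region_a"].to_numpy(int), tab["region_b"].to_numpy(int))
        values = tab["length_mm"].to_numpy(float)
    else:
        raise ValueError(f"not a distance scheme: {scheme.kind!r}")
    bin_pairs = _pairs_in_bins(scheme, values, iu)
    return _bin_means(conn.values, bin_pairs)


def homotopic_features(conn: ConnectivityMatrix,
                       pairing: HomotopicPairing) -> tuple[pd.Series, float]:
    """Connectivity of each homotopic pair plus the across-pair mean."""
    vals = pd.Series({f"{a}-{b}": float(conn.values[a, b])
                      for a, b in pairing.pairs})
    return vals, float(vals.mean())


def seed_cortical_features(conn: ConnectivityMatrix, atlas: RegionAtlas,
                           seed: str, hemisphere: str) -> pd.Series:
    """Seed-to-ipsilateral-cortical connectivity values.

    ``seed`` is a subcortical seed name (thalamus, caudate, putamen,
    pallidum, accumbens); contralateral cortical targets are excluded.
    """
    si = seed_indices(atlas, seed, hemisphere)
    targets = atlas.indices(hemisphere=hemisphere, compartment="cortical")
    return pd.Series({atlas.regions[t].name: float(conn.values[si, t])
                      for t in targets})


def idiosyncrasy(conn: ConnectivityMatrix,
                 profile: ReferenceProfile) -> float:
    """Mean squared deviation from the normative profile.

    s^2 = sum over the full R x R matrix of (x_i - xbar_i)^2 divided
    by (R*R - 1); the diagonal contributes zero since both diagonals
    are one.
    """
    if conn.r != profile.r:
        raise ValueError("conn and profile region counts differ")
    dev = conn.values - profile.mean_conn
    n = conn.r * conn.r
    return float(np.sum(dev ** 2) / (n - 1))


def normalize_timeseries(ts: np.ndarray) -> np.ndarray:
    """Min-max scale each region's series to [-1, 1].

    A positive affine map per region, so downstream Pearson
    correlations are unchanged; provided to mirror the documented
    processing order before graph measures.
    """
    ts = np.asarray(ts, dtype=float)
    lo = ts.min(axis=0)
    hi = ts.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return 2.0 * (ts - lo) / span - 1.0


def _positive_weights(conn: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    w = np.array(getattr(conn, "values", conn), dtype=float)
    w = np.where(np.isfinite(w), w, 0.0)
    np.fill_diagonal(w, 0.0)
    w[w < 0] = 0.0
    return w


def _refine_partition(w: np.ndarray, labels: np.ndarray,
                      max_passes: int = 50) -> np.ndarray:
    """Greedy single-node-move hill climb on modularity.

    Repeatedly moves one node to the community (or a new singleton)
    giving the largest positive Q gain, using incremental gain
    formulas, until no improving move exists.  Polishes partitions
    whose Louvain aggregation locked in a suboptimal merge.
    """
    n = w.shape[0]
    k = w.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        return labels
    labels = labels.copy()
    for _ in range(max_passes):
        improved = False
        for v in range(n):
            # relabel compactly and reserve an empty community
            uniq, labels = np.unique(labels, return_inverse=True)
            n_comm = len(uniq)
            onehot = np.zeros((n, n_comm + 1))
            onehot[np.arange(n), labels] = 1.0
            s_v = w[v] @ onehot                     # weight of v into c
            sigma = k @ onehot                      # total degree of c
            a = labels[v]
            s_v_a = s_v[a]                          # v's ties inside own c
            gain = (s_v - s_v_a) / two_m * 2 \
                - 2 * k[v] * (sigma - sigma[a] + k[v]) / (two_m ** 2)
            gain[a] = 0.0
            b = int(np.argmax(gain))
            if gain[b] > 1e-12:
                labels[v] = b
                improved = True
        if not improved:
            break
    return labels


def modularity_score(conn, n_restarts: int = 10,
                     random_state: int = 0) -> tuple[float, list]:
    """Maximized Newman modularity Q of the positive-weight graph.

    Negative weights are zeroed and the diagonal removed; community
    detection runs seeded Louvain restarts plus the greedy
    agglomerative candidate, each polished by a single-node-move hill
    climb, returning the best-Q partition.
    """
    w = _positive_weights(conn)
    if not w.any():
        warnings.warn("all-zero graph after thresholding; Q defined as 0",
                      stacklevel=2)
        return 0.0, [{i} for i in range(w.shape[0])]
    g = nx.from_numpy_array(w)
    candidates = []
    for k in range(n_restarts):
        candidates.append(nx.community.louvain_communities(
            g, weight="weight", seed=random_state + k))
    try:
        candidates.append(
            list(nx.community.greedy_modularity_communities(
                g, weight="weight")))
    except (ZeroDivisionError, nx.NetworkXError, StopIteration):
        pass
    best_q, best_part = -np.inf, None
    for part in candidates:
        labels = np.empty(w.shape[0], dtype=int)
        for c_i, comm in enumerate(part):
            labels[list(comm)] = c_i
        labels = _refine_partition(w, labels)
        refined = [set(np.flatnonzero(labels == c))
                   for c in np.unique(labels)]
        q = nx.community.modularity(g, refined, weight="weight")
        if q > best_q:
            best_q, best_part = q, refined
    return float(best_q), [set(int(i) for i in c) for c in best_part]


def global_efficiency(conn) -> float:
    """Weighted global efficiency of the positive-weight graph.

    Connection lengths are reciprocals of the positive weights; E is
    the mean over ordered region pairs of the reciprocal shortest-path
    length, with unreachable pairs contributing zero.
    """
    w = _positive_weights(conn)
    n = w.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 regions")
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, 0.0)
    d = shortest_path(lengths, method="auto", directed=False)
    np.fill_diagonal(d, np.inf)       # exclude self pairs
    inv = np.where(np.isfinite(d), 1.0 / d, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def network_features(conn: ConnectivityMatrix, atlas: RegionAtlas,
                     net_a, net_b=None) -> tuple[pd.Series, float]:
    """Within- or between-network pair values plus the summary mean.

    ``net_a``/``net_b`` are network labels, label sequences, or
    explicit region index arrays.  With ``net_b`` omitted, all
    unordered pairs inside ``net_a``; otherwise all cross pairs.
    """
    def resolve(net):
        if isinstance(net, str):
            net = (net,)
        if isinstance(net, (list, tuple)) and net and isinstance(net[0], str):
            return np.flatnonzero(np.isin(atlas.networks, net))
        return np.asarray(net, dtype=int)

    a = resolve(net_a)
    if net_b is None:
        pairs = [(int(i), int(j)) for ii, i in enumerate(a)
                 for j in a[ii + 1:]]
    else:
        b = resolve(net_b)
        pairs = [(int(i), int(j)) for i in a for j in b if i != j]
    vals = pd.Series({f"{i}-{j}": float(conn.values[i, j])
                      for i, j in pairs})
    return vals, float(vals.mean())


def lag_features(timeseries: np.ndarray, tr_seconds: float,
                 eval_lag_seconds: float, mask=None) -> pd.Series:
    """Signed-lag connectivity for every region pair.

    For each unordered pair (i, j), the splined cross-correlation at
    +eval_lag (j delayed) and -eval_lag, computed over the longest
    contiguous uncensored run.
    """
    c = lag_matrices(timeseries, tr_seconds, eval_lag_seconds, mask=mask)
    iu = np.triu_indices(c.shape[0], k=1)
    out = {}
    for i, j in zip(*iu):
        out[f"{i}-{j}:+"] = float(c[i, j])
        out[f"{i}-{j}:-"] = float(c[j, i])
    return pd.Series(out)


# ---------------------------------------------------------------------------
# the transformer
# ---------------------------------------------------------------------------

class ConnectivityFeatureExtractor(TransformerMixin, BaseEstimator):
    """Extract the configured feature families for each subject.

    Parameters
    ----------
    atlas, profile
        Parcellation and normative reference; both required at fit.
    methods
        Subset of :data:`ALL_METHODS` to emit (default: all).
    eval_lag_seconds
        Evaluation lag for the lagged-connectivity family.
    fd_threshold_mm, min_frac_kept
        Motion-censoring rule applied before correlation.
    include_summary_means
        Emit the across-pair summary mean of the homotopic and network
        families as additional features.

    Fitted attributes: ``strength_scheme_``, ``path_scheme_``,
    ``euclid_scheme_``, ``pairing_``, ``definitions_``,
    ``n_features_out_``.
    """

    def __init__(self, atlas=None, profile=None, methods=ALL_METHODS,
                 eval_lag_seconds=6.0, fd_threshold_mm=qc.FD_THRESHOLD_MM,
                 strength_lo=-0.2, strength_hi=0.6, strength_width=0.02,
                 euclid_width=5.0, euclid_max=165.0,
                 path_width=50.0, path_max=500.0,
                 n_modularity_restarts=10, include_summary_means=True,
                 random_state=0):
        self.atlas = atlas
        self.profile = profile
        self.methods = methods
        self.eval_lag_seconds = eval_lag_seconds
        self.fd_threshold_mm = fd_threshold_mm
        self.strength_lo = strength_lo
        self.strength_hi = strength_hi
        self.strength_width = strength_width
        self.euclid_width = euclid_width
        self.euclid_max = euclid_max
        self.path_width = path_width
        self.path_max = path_max
        self.n_modularity_restarts = n_modularity_restarts
        self.include_summary_means = include_summary_means
        self.random_state = random_state

    # -- fitting ----------------------------------------------------------
    def fit(self, X=None, y=None):
        """Derive schemes, pairing and pair index sets.

        ``X`` may be a ``(atlas, profile)`` tuple overriding the
        constructor arguments, or None.
        """
        atlas, profile = self.atlas, self.profile
        if isinstance(X, tuple) and len(X) == 2:
            atlas, profile = X
        if atlas is None or profile is None:
            raise ValueError("atlas and profile are required to fit")
        if atlas.n_regions != profile.r:
            raise ValueError("atlas and profile region counts differ")
        self.atlas_, self.profile_ = atlas, profile
        methods = set(self.methods)
        r = atlas.n_regions
        iu = np.triu_indices(r, k=1)
        self._blocks = []

        def add_block(method, anchors, pair_arrays=None):
            self._blocks.append((method, anchors, pair_arrays))

        if "strength_bin" in methods:
            self.strength_scheme_ = make_strength_bins(
                profile, self.strength_lo, self.strength_hi,
                self.strength_width)
            bp = _pairs_in_bins(self.strength_scheme_,
                                profile.mean_conn[iu], iu)
            add_block("strength_bin", [f"bin{b:02d}" for b in bp], bp)
        if "path_bin" in methods:
            self.path_scheme_ = make_distance_bins(
                profile, "path_length", self.path_width, self.path_max)
            tab = profile.path_lengths
            piu = (tab["region_a"].to_numpy(int),
                   tab["region_b"].to_numpy(int))
            bp = _pairs_in_bins(self.path_scheme_,
                                tab["length_mm"].to_numpy(float), piu)
            add_block("path_bin", [f"bin{b:02d}" for b in bp], bp)
        if "euclid_bin" in methods:
            self.euclid_scheme_ = make_distance_bins(
                profile, "euclidean_distance", self.euclid_width,
                self.euclid_max)
            bp = _pairs_in_bins(self.euclid_scheme_,
                                profile.centroid_dist[iu], iu)
            add_block("euclid_bin", [f"bin{b:02d}" for b in bp], bp)
        if "homotopic" in methods:
            self.pairing_ = find_homotopic_pairs(atlas)
            self._add_pair_block("homotopic", self.pairing_.pairs)
        for fam, seeds in (("corticostriatal", STRIATAL_SEEDS),
                           ("thalamocortical", ("thalamus",))):
            if fam not in methods:
                continue
            rows, cols, anchors = [], [], []
            for sname in seeds:
                for h in ("left", "right"):
                    try:
                        si = seed_indices(atlas, sname, h)
                    except KeyError:
                        continue
                    for t in atlas.indices(hemisphere=h,
                                           compartment="cortical"):
                        rows.append(si)
                        cols.append(int(t))
                        anchors.append(
                            f"{atlas.regions[si].name}|"
                            f"{atlas.regions[t].name}")
            add_block(fam, anchors, (np.array(rows), np.array(cols)))
        dmn_idx = np.flatnonzero((atlas.networks == "default")
                                 & (atlas.compartments == "cortical"))
        sal_idx = np.flatnonzero(
            np.isin(atlas.networks, SALIENCE_SET_LABELS)
            & (atlas.compartments == "cortical"))
        self.dmn_indices_, self.salience_indices_ = dmn_idx, sal_idx
        if "dmn_within" in methods:
            self._add_pair_block("dmn_within", self._within_pairs(dmn_idx))
        if "salience_within" in methods:
            self._add_pair_block("salience_within",
                                 self._within_pairs(sal_idx))
        if "dmn_salience_between" in methods:
            pairs = [(int(i), int(j)) for i in dmn_idx for j in sal_idx
                     if i != j]
            self._add_pair_block("dmn_salience_between", pairs)
        for scalar in SCALAR_METHODS:
            if scalar in methods:
                add_block(scalar, ["value"], None)
        if "lag" in methods:
            anchors = []
            for i, j in zip(*iu):
                anchors.append(f"{self._pair_name(i, j)}:+")
                anchors.append(f"{self._pair_name(i, j)}:-")
            add_block("lag", anchors, iu)
        self.definitions_ = [
            FeatureDefinition(f"{method}:{anchor}", method, anchor)
            for method, anchors, _ in self._blocks for anchor in anchors
        ]
        self.n_features_out_ = len(self.definitions_)
        return self

    def _pair_name(self, i, j):
        return (f"{self.atlas_.regions[int(i)].name}|"
                f"{self.atlas_.regions[int(j)].name}")

    def _within_pairs(self, idx):
        return [(int(a), int(b)) for ai, a in enumerate(idx)
                for b in idx[ai + 1:]]

    def _add_pair_block(self, method, pairs):
        anchors = [self._pair_name(i, j) for i, j in pairs]
        if self.include_summary_means:
            anchors = anchors + ["mean"]
        self._blocks.append((method, anchors,
                             (np.array([p[0] for p in pairs]),
                              np.array([p[1] for p in pairs]))))

    # -- transforming -----------------------------------------------------
    def transform(self, X) -> FeatureTable:
        """Compute features for a cohort or list of subject records."""
        subjects = getattr(X, "subjects", X)
        if not hasattr(self, "definitions_"):
            raise RuntimeError("extractor is not fitted")
        values = np.full((len(subjects), self.n_features_out_), np.nan)
        ids = []
        for s_i, subj in enumerate(subjects):
            ids.append(subj.subject_id)
            values[s_i] = self._subject_row(subj)
        df = pd.DataFrame(values, index=ids,
                          columns=[d.feature_id for d in self.definitions_])
        return FeatureTable(values=df, definitions=self.definitions_)

    def fit_transform(self, X, y=None, **kwargs):
        # X is the cohort; fitting uses the constructor's atlas/profile
        return self.fit().transform(X)

    def _subject_row(self, subj) -> np.ndarray:
        mask = qc.censor_volumes(subj.fd_trace,
                                 threshold=self.fd_threshold_mm)
        conn = connectivity_matrix(subj.timeseries, mask,
                                   subject_id=subj.subject_id)
        out = []
        mean_families = ("homotopic", "dmn_within", "salience_within",
                         "dmn_salience_between")
        for method, anchors, pair_arrays in self._blocks:
            if method in ("strength_bin", "path_bin", "euclid_bin"):
                means = _bin_means(conn.values, pair_arrays)
                out.append(means.to_numpy())
            elif method in ("corticostriatal", "thalamocortical"):
                rows, cols = pair_arrays
                out.append(conn.values[rows, cols])
            elif method in mean_families:
                rows, cols = pair_arrays
                vals = conn.values[rows, cols]
                if self.include_summary_means:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        vals = np.append(vals, np.nanmean(vals))
                out.append(vals)
            elif method == "idiosyncrasy":
                out.append([idiosyncrasy(conn, self.profile_)])
            elif method == "modularity":
                q, _ = modularity_score(
                    conn, n_restarts=self.n_modularity_restarts,
                    random_state=self.random_state)
                out.append([q])
            elif method == "global_efficiency":
                out.append([global_efficiency(conn)])
            elif method == "lag":
                out.append(self._lag_values(subj, mask, pair_arrays))
            else:
                raise RuntimeError(f"unknown feature block {method!r}")
        return np.concatenate([np.asarray(v, dtype=float) for v in out])

    def _lag_values(self, subj, mask, iu) -> np.ndarray:
        _, n_min = required_length(subj.tr, self.eval_lag_seconds)
        try:
            c = lag_matrices(subj.timeseries, subj.tr,
                             self.eval_lag_seconds, mask=mask)
        except ValueError:
            warnings.warn(
                f"subject {subj.subject_id}: longest uncensored run "
                f"shorter than {n_min} volumes; lag features missing",
                stacklevel=2)
            return np.full(2 * iu[0].size, np.nan)
        vals = np.empty(2 * iu[0].size)
        vals[0::2] = c[iu]
        vals[1::2] = c[iu[1], iu[0]]
        return vals
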