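"""Parcellation model and geometry-derived structures.

A :class:`RegionAtlas` holds the region metadata (name, hemisphere,
compartment, resting-state network label, centroid in mm, x increasing
rightward) for a parcellation such as the combined 333-cortical /
14-subcortical / 14-cerebellar scheme (361 regions).  From it we derive

* homotopic region pairs, by mirroring each left-hemisphere centroid
  across the midsagittal plane and keeping mutual nearest neighbours;
* bin schemes over normative connectivity strength, Euclidean
  centroid distance, and structural (fiber) path length, used to group
  region pairs into strata for per-bin connectivity features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

HEMISPHERES = ("left", "right", "midline")
COMPARTMENTS = ("cortical", "subcortical", "cerebellar")

#: compartment counts of the full combined parcellation
PAPER_COMPLETE_COUNTS = (333, 14, 14)


class AtlasValidationError(ValueError):
    """Raised when region metadata violates atlas invariants."""


@dataclass(frozen=True)
class Region:
    """One parcel: metadata plus its centroid in template space (mm)."""

    region_id: int
    name: str
    hemisphere: str
    compartment: str
    network: str | None
    centroid: tuple[float, float, float]

    def __post_init__(self):
        if self.hemisphere not in HEMISPHERES:
            raise AtlasValidationError(
                f"region {self.name!r}: hemisphere {self.hemisphere!r} "
                f"not in {HEMISPHERES}")
        if self.compartment not in COMPARTMENTS:
            raise AtlasValidationError(
                f"region {self.name!r}: compartment {self.compartment!r} "
                f"not in {COMPARTMENTS}")
        c = np.asarray(self.centroid, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise AtlasValidationError(
                f"region {self.name!r}: centroid must be a finite 3-vector")


@dataclass
class RegionAtlas:
    """Ordered collection of regions with derived array views."""

    regions: list[Region]

    def __post_init__(self):
        ids = [r.region_id for r in self.regions]
        names = [r.name for r in self.regions]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise AtlasValidationError(f"duplicate region_id(s): {dup}")
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise AtlasValidationError(f"duplicate region name(s): {dup}")

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def centroids(self) -> np.ndarray:
        """(R, 3) centroid array in atlas order."""
        return np.array([r.centroid for r in self.regions], dtype=float)

    @property
    def hemispheres(self) -> np.ndarray:
        return np.array([r.hemisphere for r in self.regions])

    @property
    def compartments(self) -> np.ndarray:
        return np.array([r.compartment for r in self.regions])

    @property
    def networks(self) -> np.ndarray:
        return np.array(
            [r.network if r.network is not None else "" for r in self.regions])

    @property
    def counts(self) -> tuple[int, int, int]:
        """(n_cortical, n_subcortical, n_cerebellar)."""
        comp = self.compartments
        return tuple(int(np.sum(comp == c)) for c in COMPARTMENTS)

    @property
    def is_paper_complete(self) -> bool:
        """Whether compartment counts match the full 361-region scheme."""
        return self.counts == PAPER_COMPLETE_COUNTS

    def indices(self, *, hemisphere=None, compartment=None, network=None):
        """Positional indices of regions matching all given filters."""
        mask = np.ones(self.n_regions, dtype=bool)
        if hemisphere is not None:
            mask &= self.hemispheres == hemisphere
        if compartment is not None:
            mask &= self.compartments == compartment
        if network is not None:
            mask &= self.networks == network
        return np.flatnonzero(mask)

    def index_of(self, name: str) -> int:
        for i, r in enumerate(self.regions):
            if r.name == name:
                return i
        raise KeyError(f"no region named {name!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(id=r.region_id, name=r.name, hemisphere=r.hemisphere,
                 compartment=r.compartment,
                 network=r.network if r.network is not None else "",
                 x=r.centroid[0], y=r.centroid[1], z=r.centroid[2])
            for r in self.regions
        ]
        return pd.DataFrame(rows)


def build_atlas(region_records) -> RegionAtlas:
    """Validate tabular region metadata into a :class:`RegionAtlas`.

    Parameters
    ----------
    region_records : DataFrame or iterable of mappings
        One record per region with fields ``id, name, hemisphere,
        compartment, network, x, y, z``.  ``network`` may be empty.

    An atlas whose compartment counts deviate from (333, 14, 14) is
    usable but flagged via a warning and ``is_paper_complete == False``.
    """
    if isinstance(region_records, pd.DataFrame):
        records = region_records.to_dict("records")
    else:
        records = [dict(r) for r in region_records]
    regions = []
    for rec in records:
        missing = {"id", "name", "hemisphere", "compartment", "x", "y", "z"} \
            - set(rec)
        if missing:
            raise AtlasValidationError(
                f"record {rec.get('name', rec)!r} missing fields "
                f"{sorted(missing)}")
        for axis in ("x", "y", "z"):
            if rec[axis] is None or (isinstance(rec[axis], float)
                                     and not np.isfinite(rec[axis])):
                raise AtlasValidationError(
                    f"record {rec['name']!r}: missing/non-finite "
                    f"centroid {axis}")
        net = rec.get("network", "")
        if net is None or (isinstance(net, float) and np.isnan(net)):
            net = ""
        regions.append(Region(
            region_id=int(rec["id"]), name=str(rec["name"]),
            hemisphere=str(rec["hemisphere"]),
            compartment=str(rec["compartment"]),
            network=str(net) or None,
            centroid=(float(rec["x"]), float(rec["y"]), float(rec["z"])),
        ))
    atlas = RegionAtlas(regions)
    if not atlas.is_paper_complete:
        warnings.warn(
            f"atlas compartment counts {atlas.counts} deviate from "
            f"{PAPER_COMPLETE_COUNTS}; atlas is usable but not "
            "paper-complete", stacklevel=2)
    return atlas


def read_atlas(path) -> RegionAtlas:
    """Read an atlas from a tab-separated file (see :func:`build_atlas`)."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return build_atlas(df)


def write_atlas(atlas: RegionAtlas, path) -> None:
    atlas.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# homotopic pairing
# ---------------------------------------------------------------------------

@dataclass
class HomotopicPairing:
    """Mutualized left/right mirror pairs.

    ``pairs`` holds (left_index, right_index) positional index tuples;
    ``excluded`` holds indices of regions without a mutual mirror
    partner (midline regions are always excluded).
    """

    pairs: list[tuple[int, int]]
    excluded: list[int]

    def __len__(self) -> int:
        return len(self.pairs)

    def partner(self, idx: int) -> int | None:
        for a, b in self.pairs:
            if a == idx:
                return b
            if b == idx:
                return a
        return None


def find_homotopic_pairs(atlas: RegionAtlas) -> HomotopicPairing:
    """Identify homotopic region pairs by mirror-image nearest neighbours.

    Each left-hemisphere centroid is reflected across the midsagittal
    plane (x -> -x) and matched to the nearest right-hemisphere
    centroid; a pair is kept only when the reverse lookup agrees
    (mutual nearest), which prevents many-to-one pairings.  Midline
    regions never participate.
    """
    hemi = atlas.hemispheres
    left = np.flatnonzero(hemi == "left")
    right = np.flatnonzero(hemi == "right")
    if len(left) == 0 or len(right) == 0:
        raise AtlasValidationError(
            "homotopic pairing needs at least one region per hemisphere")
    cent = atlas.centroids
    if np.allclose(cent, cent[0]):
        raise AtlasValidationError(
            "degenerate geometry: all centroids identical")
    mirror = cent.copy()
    mirror[:, 0] = -mirror[:, 0]
    # left-mirrored vs right, both directions
    d_lr = cdist(mirror[left], cent[right])       # (L, R)
    d_rl = cdist(mirror[right], cent[left])       # (R, L)
    best_r_for_l = np.argmin(d_lr, axis=1)
    best_l_for_r = np.argmin(d_rl, axis=1)
    pairs, paired = [], set()
    for li, rj in enumerate(best_r_for_l):
        if best_l_for_r[rj] == li:
            pairs.append((int(left[li]), int(right[rj])))
            paired.add(int(left[li]))
            paired.add(int(right[rj]))
    excluded = [i for i in range(atlas.n_regions) if i not in paired]
    return HomotopicPairing(pairs=pairs, excluded=excluded)


# ---------------------------------------------------------------------------
# bin schemes
# ---------------------------------------------------------------------------

BIN_KINDS = ("strength", "euclidean_distance", "path_length")


@dataclass
class BinScheme:
    """Equal-width bins fit on reference data, with empty bins dropped.

    Intervals are left-closed/right-open, the final bin closed, so
    boundary values map deterministically.  ``dropped_bins`` records
    the indices (in the pre-drop numbering) removed for emptiness;
    ``n_out_of_range`` counts reference values outside [lo, hi].
    """

    kind: str
    edges: np.ndarray
    dropped_bins: list[int] = field(default_factory=list)
    n_out_of_range: int = 0

    @property
    def bin_count(self) -> int:
        """Number of bins before drops."""
        return len(self.edges) - 1

    @property
    def retained_bins(self) -> list[int]:
        return [i for i in range(self.bin_count) if i not in self.dropped_bins]

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Bin index per value; -1 for out-of-range values.

        Assignment ignores drops: a value falling in a dropped bin gets
        that bin's index (callers filter on ``retained_bins``).
        """
        v = np.asarray(values, dtype=float)
        idx = np.searchsorted(self.edges, v, side="right") - 1
        # final bin is closed on the right
        idx[v == self.edges[-1]] = self.bin_count - 1
        idx[(v < self.edges[0]) | (v > self.edges[-1])] = -1
        return idx


def _fit_scheme(kind: str, values: np.ndarray, lo: float, hi: float,
                width: float) -> BinScheme:
    if width <= 0:
        raise ValueError("bin width must be positive")
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    n_bins = int(round((hi - lo) / width))
    edges = lo + width * np.arange(n_bins + 1)
    edges[-1] = hi
    scheme = BinScheme(kind=kind, edges=edges)
    idx = scheme.assign(values)
    scheme.n_out_of_range = int(np.sum(idx < 0))
    counts = np.bincount(idx[idx >= 0], minlength=n_bins)
    scheme.dropped_bins = [i for i in range(n_bins) if counts[i] == 0]
    if scheme.n_out_of_range:
        warnings.warn(
            f"{scheme.n_out_of_range} reference value(s) outside "
            f"[{lo}, {hi}] assigned to no {kind} bin", stacklevel=3)
    return scheme


def upper_triangle(matrix: np.ndarray) -> np.ndarray:
    """Off-diagonal upper-triangle values of a square matrix."""
    m = np.asarray(matrix)
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def make_strength_bins(reference, lo: float = -0.2, hi: float = 0.6,
                       width: float = 0.02) -> BinScheme:
    """Bin normative mean connectivity into equal-width strength strata.

    Defaults give 40 bins of .02 spanning [-.2, .6]; bins with no
    reference region pair are dropped (self pairs never participate).

    ``reference`` is a :class:`~fcmethods.features.ReferenceProfile`
    or a bare symmetric matrix of normative mean connectivity.
    """
    mean_conn = getattr(reference, "mean_conn", reference)
    values = upper_triangle(np.asarray(mean_conn, dtype=float))
    return _fit_scheme("strength", values, lo, hi, width)


def make_distance_bins(atlas_or_profile, kind: str,
                       width: float | None = None,
                       hi: float | None = None) -> BinScheme:
    """Bin region pairs by Euclidean centroid distance or fiber path length.

    ``kind='euclidean_distance'`` uses all centroid pairs with 5-mm bins
    over [0, 165]; ``kind='path_length'`` uses only structurally
    connected pairs (the path-length table) with 50-mm bins over
    [0, 500].  Distances above ``hi`` are excluded and reported;
    negative distances are an error.
    """
    if kind == "euclidean_distance":
        width = 5.0 if width is None else width
        hi = 165.0 if hi is None else hi
        if hasattr(atlas_or_profile, "centroid_dist"):
            dist = np.asarray(atlas_or_profile.centroid_dist, dtype=float)
        else:
            cent = atlas_or_profile.centroids
            dist = cdist(cent, cent)
        values = upper_triangle(dist)
    elif kind == "path_length":
        width = 50.0 if width is None else width
        hi = 500.0 if hi is None else hi
        table = getattr(atlas_or_profile, "path_lengths", atlas_or_profile)
        values = np.asarray(pd.DataFrame(table)["length_mm"], dtype=float)
    else:
        raise ValueError(f"kind must be euclidean_distance or path_length, "
                         f"got {kind!r}")
    if np.any(values < 0):
        raise ValueError(f"negative {kind} value(s) encountered")
    return _fit_scheme(kind, values, 0.0, hi, width)
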