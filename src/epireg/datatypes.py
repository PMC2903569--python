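"""Core data types shared across the pipeline.

The pipeline works on a fixed, ordered panel of cell lines: every profile
vector (methylation percentages or expression values) is aligned to that
order.  Coordinates are 1-based and ranges inclusive at both ends,
matching base-pair counting; a BED-style reader converts on input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Panel:
    """An ordered panel of cell lines, optionally labelled by molecular subtype.

    Parameters
    ----------
    cell_lines
        Unique cell-line names; the order is shared by every profile vector
        in the pipeline.
    subtypes
        Optional per-line label (e.g. ``"basal A"``, ``"basal B"``,
        ``"luminal"``); ``None`` entries mean unknown.
    """

    cell_lines: tuple[str, ...]
    subtypes: tuple[str | None, ...] | None = None

    def __post_init__(self) -> None:
        if len(set(self.cell_lines)) != len(self.cell_lines):
            dupes = sorted({c for c in self.cell_lines if list(self.cell_lines).count(c) > 1})
            raise ValueError(f"duplicate cell-line names in panel: {dupes}")
        if self.subtypes is not None and len(self.subtypes) != len(self.cell_lines):
            raise ValueError("subtypes length must match cell_lines length")

    def __len__(self) -> int:
        return len(self.cell_lines)

    def index_of(self, names: list[str] | tuple[str, ...]) -> np.ndarray:
        """Column indices of `names` in this panel's order."""
        pos = {c: i for i, c in enumerate(self.cell_lines)}
        return np.array([pos[n] for n in names], dtype=int)


@dataclass
class MethylationSite:
    """One CpG site: genomic coordinate plus per-cell-line methylation.

    ``profile`` holds percentages in [0, 100]; missing measurements are NaN.
    """

    site_id: str
    chromosome: str
    position: int  # 1-based
    profile: np.ndarray

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=float)
        if self.position < 1:
            raise ValueError(f"site {self.site_id}: position must be >= 1, got {self.position}")
        finite = self.profile[np.isfinite(self.profile)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError(f"site {self.site_id}: methylation outside [0, 100]")


@dataclass
class ExpressionProbeSet:
    """One expression probe set mapped to a gene and a genomic range.

    A gene may have multiple probe sets covering different portions of a
    chromosome; all are kept and associated independently.
    """

    probeset_id: str
    gene: str
    chromosome: str
    start: int  # 1-based, inclusive
    end: int    # 1-based, inclusive
    profile: np.ndarray

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=float)
        if self.start > self.end:
            raise ValueError(
                f"probe set {self.probeset_id}: start {self.start} > end {self.end}"
            )


@dataclass
class Region:
    """A proximity group of CpG sites on one chromosome.

    Members are consecutive sites whose successive positions differ by at
    most the gap threshold (2,000 bp by default).
    """

    region_id: str
    chromosome: str
    member_sites: list[str]
    span: tuple[int, int]


@dataclass
class PCAModel:
    """Panel-wide PCA of the site-by-cell-line methylation matrix.

    ``n_kept`` is the smallest component count whose cumulative explained
    variance reaches ``variance_fraction``.
    """

    components: np.ndarray       # (n_kept, n_lines) orthonormal loadings
    mean: np.ndarray             # per-cell-line mean used for centering
    n_kept: int
    variance_fraction: float
    explained_variance_ratio: np.ndarray = field(repr=False, default=None)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project site profiles (rows) into the retained component space."""
        return (np.asarray(X, dtype=float) - self.mean) @ self.components.T


@dataclass
class ClusterModel:
    """Similarity-clustering result for one proximity region.

    ``representatives[c]`` is cluster *c*'s mean methylation profile over the
    original percentages (not PCA coordinates).  ``anchors[c]`` is the member
    site closest to the cluster's positional centroid, used downstream as
    the representative methylation site's position.
    """

    region_id: str
    chromosome: str
    sigma: float | None
    k: int
    assignments: dict[str, int]           # site_id -> cluster index
    compactness: float | None             # W/B at the selected pair; None for single-cluster
    representatives: np.ndarray           # (k, n_lines)
    anchors: list[tuple[str, int]]        # per cluster: (site_id, position)

    def cluster_sizes(self) -> np.ndarray:
        sizes = np.zeros(self.k, dtype=int)
        for c in self.assignments.values():
            sizes[c] += 1
        return sizes


@dataclass
class Association:
    """One representative methylation profile paired with one probe set."""

    assoc_id: str
    region_id: str
    cluster: int
    gene: str
    probeset_id: str
    anchor_site: str
    anchor_chrom: str
    anchor_pos: int
    distance_to_probeset: int             # 0 if the anchor falls inside the range
    M_profile: np.ndarray                 # methylation %, per cell line
    E_profile: np.ndarray                 # normalized expression, per cell line


@dataclass
class FitResult:
    """Constrained sigmoid fit of expression on methylation.

    The model is the monotone-decreasing logistic
    ``E_fit(M) = a / (1 + exp(b * (M - c)))`` with a in [0, 200], b >= 0,
    c in [-50, 150].  ``R = SSR / (SSR + SSE)`` lies in [0, 1]; 1 means a
    perfect fit, 0 the degenerate constant fit.
    """

    a: float
    b: float
    c: float
    E_fit: np.ndarray
    SSR: float
    SSE: float
    R: float
    n_pairs: int


@dataclass
class RankedGene:
    """A gene with its best (highest-R) association and permutation p-value."""

    gene: str
    assoc_id: str
    region_id: str
    cluster: int
    probeset_id: str
    R: float
    p_value: float
    fit: FitResult


@dataclass
class SyntheticTruth:
    """Ground truth of a generated panel; fully determined by the seed."""

    seed: int
    region_of_site: dict[str, int]
    cluster_of_site: dict[str, int]       # global (region, subgroup) index
    regulated_genes: list[str]
    curve_params: dict[str, tuple[float, float, float]]   # gene -> (a, b, c)
    noise_sd: float
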