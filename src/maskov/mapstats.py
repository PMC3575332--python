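"""Map-building statistics for testcross progenies.

Everything downstream of imputation: recombination accounting, genotype
binning, two-point linkage (recombination fraction and LOD), single-linkage
grouping at a LOD threshold, Kosambi map distances along a given order, and
the chi-squared segregation-distortion scan against the 1:1 testcross
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import chi2 as _chi2_dist
from sklearn.base import BaseEstimator, ClusterMixin

from .model import HET, HOM, MISSING, GenotypeMatrix, infer_phases, encode_group

__all__ = [
    "TwoPointResult",
    "MarkerBin",
    "LinkageGroupSummary",
    "count_recombinations",
    "recombination_counts",
    "mean_recombinations",
    "percent_reduction",
    "bin_markers",
    "recombination_fraction",
    "two_point_lod",
    "group_markers",
    "LinkageGrouper",
    "kosambi_cM",
    "map_length_along_order",
    "chi_square_scan",
    "order_markers_greedy",
    "CHI2_THRESHOLDS",
]


# -- recombination accounting -------------------------------------------

def count_recombinations(v: np.ndarray) -> int:
    """Number of sign changes along an ordered encoded vector.

    Missing values (0) are skipped: transitions are counted between
    consecutive non-missing entries.
    """
    v = np.asarray(v)
    nz = v[v != 0]
    if len(nz) < 2:
        return 0
    return int(np.sum(nz[1:] != nz[:-1]))


def recombination_counts(matrix: GenotypeMatrix, phases: np.ndarray | None = None) -> pd.Series:
    """Per-individual recombination totals summed over all linkage groups."""
    if phases is None:
        phases = matrix.phases if matrix.phases is not None else infer_phases(matrix)
    totals = np.zeros(matrix.n_individuals, dtype=np.int64)
    for g in matrix.groups():
        enc, _, _ = encode_group(matrix, phases, g)
        for j in range(matrix.n_individuals):
            totals[j] += count_recombinations(enc[:, j])
    return pd.Series(totals, index=matrix.individual_ids, name="recombinations")


def mean_recombinations(matrix: GenotypeMatrix, phases: np.ndarray | None = None) -> float:
    """Mean perceived recombination events per individual across all groups."""
    return float(recombination_counts(matrix, phases).mean())


def percent_reduction(before: float, after: float) -> float:
    """100*(before - after)/before, reported to one decimal."""
    if before <= 0:
        raise ValueError("before must be > 0")
    return round(100.0 * (before - after) / before, 1)


# -- genotype bins -------------------------------------------------------

@dataclass
class MarkerBin:
    """A set of markers with identical genotype vectors, mapped as one locus."""

    bin_id: int
    marker_ids: list[str]
    representative: str  # first member in map order
    genotype: np.ndarray  # shared call vector across individuals
    position: int  # rank of the bin along the group


def bin_markers(matrix: GenotypeMatrix, group) -> list[MarkerBin]:
    """Group a linkage group's markers into bins of identical genotypes.

    Requires imputed (missing-free) data within the group; bins are ordered
    by their first member's order rank and partition the group's markers.
    """
    rows = matrix.group_marker_indices(group)
    calls = matrix.calls[rows]
    if (calls == MISSING).any():
        raise ValueError(
            f"group {group!r} still contains missing calls; impute before binning"
        )
    bins: list[MarkerBin] = []
    seen: dict[bytes, int] = {}
    for k, r in enumerate(rows):
        key = calls[k].tobytes()
        if key in seen:
            bins[seen[key]].marker_ids.append(matrix.marker_ids[r])
        else:
            seen[key] = len(bins)
            bins.append(
                MarkerBin(
                    bin_id=len(bins),
                    marker_ids=[matrix.marker_ids[r]],
                    representative=matrix.marker_ids[r],
                    genotype=calls[k].copy(),
                    position=len(bins),
                )
            )
    return bins


# -- two-point linkage ---------------------------------------------------

@dataclass
class TwoPointResult:
    """Two-point recombination estimate between a marker pair.

    ``r_hat`` is recombinants / informative meioses, folded to [0, 0.5] by
    adopting the complementary phase when the raw fraction exceeds 0.5
    (``phase_flipped`` records this).  ``lod`` is the log10 likelihood ratio
    of linkage at ``r_hat`` against free recombination (r = 0.5).
    ``undefined`` flags pairs with no informative meioses.
    """

    r_hat: float
    lod: float
    n_informative: int
    n_recombinant: int
    phase_flipped: bool = False
    undefined: bool = False


def _lod(R: int, n: int) -> float:
    """Testcross two-point LOD with r_hat = R/n against r = 0.5."""
    if n == 0:
        return 0.0
    r = R / n
    lod = 0.0
    if R > 0:
        lod += R * np.log10(r / 0.5)
    if n - R > 0:
        lod += (n - R) * np.log10((1 - r) / 0.5)
    return float(lod)


def two_point(v1: np.ndarray, v2: np.ndarray) -> TwoPointResult:
    """Recombination fraction and LOD between two encoded vectors.

    Individuals missing at either marker are skipped.  A raw fraction above
    0.5 indicates the markers are in opposite phase; the complement is
    adopted and flagged.
    """
    v1 = np.asarray(v1)
    v2 = np.asarray(v2)
    if v1.shape != v2.shape:
        raise ValueError("vectors must be aligned on the same individuals")
    inf = (v1 != 0) & (v2 != 0)
    n = int(inf.sum())
    if n == 0:
        return TwoPointResult(np.nan, np.nan, 0, 0, undefined=True)
    R = int(np.sum(v1[inf] != v2[inf]))
    flipped = False
    if R > n - R:
        R = n - R
        flipped = True
    return TwoPointResult(
        r_hat=R / n,
        lod=_lod(R, n),
        n_informative=n,
        n_recombinant=R,
        phase_flipped=flipped,
    )


def recombination_fraction(v1: np.ndarray, v2: np.ndarray) -> TwoPointResult:
    return two_point(v1, v2)


def two_point_lod(v1: np.ndarray, v2: np.ndarray) -> TwoPointResult:
    return two_point(v1, v2)


# -- linkage grouping ----------------------------------------------------

def _pairwise_two_point(enc: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised pairwise (r_hat, lod, n) over a markers x individuals array."""
    enc = np.asarray(enc, dtype=np.float64)
    nz = (enc != 0).astype(np.float64)
    n = nz @ nz.T  # informative meioses per pair
    s = enc @ enc.T  # concordant - discordant
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (n - s) / 2.0
        R = np.minimum(R, n - R)  # fold: complementary phase when r > 0.5
        r = np.where(n > 0, R / np.maximum(n, 1), np.nan)
        lod = np.zeros_like(r)
        pos = R > 0
        lod = np.where(pos, R * np.log10(np.maximum(r, 1e-300) / 0.5), 0.0)
        lod += np.where(n - R > 0, (n - R) * np.log10((1 - np.where(n > 0, r, 0)) / 0.5), 0.0)
        lod = np.where(n > 0, lod, np.nan)
    return r, lod, n.astype(np.int64)


def group_markers(
    matrix_or_encoded,
    min_lod: float = 7.0,
    max_r: float = 0.35,
    phases: np.ndarray | None = None,
) -> np.ndarray:
    """Single-linkage grouping of markers into linkage groups.

    Two markers are joined when their two-point LOD is at least ``min_lod``
    *and* the recombination fraction is at most ``max_r``; linkage groups
    are the connected components of that graph.  Accepts a
    :class:`GenotypeMatrix` (encoded under all-``1-`` phases; the fold to
    r <= 0.5 makes grouping phase-agnostic) or a markers x individuals
    encoded array.  Returns per-marker integer labels.
    """
    if isinstance(matrix_or_encoded, GenotypeMatrix):
        m = matrix_or_encoded
        ph = np.ones(m.n_markers, dtype=np.int8) if phases is None else phases
        from .model import _encode_calls

        enc = _encode_calls(m.calls, ph)
    else:
        enc = np.asarray(matrix_or_encoded, dtype=np.int8)
    r, lod, n = _pairwise_two_point(enc)
    adj = (lod >= min_lod) & (r <= max_r) & (n > 0)
    np.fill_diagonal(adj, False)
    _, labels = connected_components(sparse.csr_matrix(adj), directed=False)
    return labels


class LinkageGrouper(ClusterMixin, BaseEstimator):
    """scikit-learn style clusterer wrapping :func:`group_markers`.

    ``fit(X)`` expects a markers x individuals phase-encoded array over
    {1, 0, -1} (the markers are the samples being clustered); after fitting,
    ``labels_`` holds the linkage-group label of every marker and
    ``n_groups_`` the number of groups.
    """

    def __init__(self, min_lod: float = 7.0, max_r: float = 0.35):
        self.min_lod = min_lod
        self.max_r = max_r

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (markers x individuals)")
        self.labels_ = group_markers(X, min_lod=self.min_lod, max_r=self.max_r)
        self.n_groups_ = int(self.labels_.max()) + 1 if len(self.labels_) else 0
        self.n_features_in_ = X.shape[1]
        return self


# -- map distances -------------------------------------------------------

def kosambi_cM(r):
    """Kosambi map distance d = 25*ln((1+2r)/(1-2r)) in centi-Morgans."""
    r = np.asarray(r, dtype=np.float64)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))
    return float(d) if d.ndim == 0 else d


@dataclass
class LinkageGroupSummary:
    lg: object
    length_cM: float
    n_markers: int
    n_bins: int
    cM_per_marker: float
    cM_per_bin: float


def map_length_along_order(
    bins: Sequence[MarkerBin], lg=None, encoded: np.ndarray | None = None
) -> LinkageGroupSummary:
    """Map length as the sum of adjacent-bin Kosambi distances.

    ``encoded`` optionally provides the bins' representative genotype
    vectors already phase-encoded (bins x individuals); otherwise each bin's
    call vector is encoded under phase ``1-`` — adjacent-bin r is folded to
    [0, 0.5] so the phase convention does not affect the length.  A single
    bin yields length 0.
    """
    n_bins = len(bins)
    n_markers = sum(len(b.marker_ids) for b in bins)
    if encoded is None:
        enc = np.array(
            [np.where(b.genotype == HET, 1, np.where(b.genotype == HOM, -1, 0)) for b in bins],
            dtype=np.int8,
        )
    else:
        enc = np.asarray(encoded, dtype=np.int8)
    length = 0.0
    for a, b in zip(range(n_bins - 1), range(1, n_bins)):
        tp = two_point(enc[a], enc[b])
        if tp.undefined:
            raise ValueError(f"no informative meioses between bins {a} and {b}")
        if tp.r_hat == 0.0 and np.array_equal(enc[a], enc[b]):
            raise AssertionError("identical consecutive bins should have been collapsed")
        length += kosambi_cM(tp.r_hat)
    return LinkageGroupSummary(
        lg=lg,
        length_cM=length,
        n_markers=n_markers,
        n_bins=n_bins,
        cM_per_marker=length / n_markers if n_markers else 0.0,
        cM_per_bin=length / n_bins if n_bins else 0.0,
    )


# -- segregation distortion ----------------------------------------------

#: chi-squared (df=1) critical values at P = 0.05, 0.01, 0.001
CHI2_THRESHOLDS = {"0.05": 3.841, "0.01": 6.635, "0.001": 10.828}


def chi_square_scan(
    matrix: GenotypeMatrix, positions_cM: dict | None = None
) -> pd.DataFrame:
    """Per-marker chi-squared test against the 1:1 testcross expectation.

    For each marker the two class counts (het-like vs hom-like among
    non-missing individuals) give ``chi2 = (a-b)^2/(a+b)`` with one degree
    of freedom.  ``positions_cM`` optionally maps marker_id -> map position
    so the scan can be ordered and plotted along each linkage group;
    ``sig_level`` marks the strongest fixed threshold exceeded (3.841 /
    6.635 / 10.828).  Markers with no non-missing calls are flagged with
    NaN statistics.
    """
    recs = []
    for g in matrix.groups():
        for r in matrix.group_marker_indices(g):
            row = matrix.calls[r]
            a = int(np.sum(row == HET))
            b = int(np.sum(row == HOM))
            n = a + b
            if n == 0:
                stat, p = np.nan, np.nan
            else:
                stat = (a - b) ** 2 / n
                p = float(_chi2_dist.sf(stat, df=1))
            sig = ""
            if n > 0:
                for label, thr in (("0.001", 10.828), ("0.01", 6.635), ("0.05", 3.841)):
                    if stat > thr:
                        sig = label
                        break
            recs.append(
                {
                    "marker_id": matrix.marker_ids[r],
                    "lg": g,
                    "position_cM": (
                        np.nan if positions_cM is None else positions_cM.get(matrix.marker_ids[r], np.nan)
                    ),
                    "n": n,
                    "count_class1": a,
                    "count_class2": b,
                    "chi2": stat,
                    "p": p,
                    "sig_level": sig,
                }
            )
    df = pd.DataFrame(recs)
    if positions_cM is not None and len(df):
        df = df.sort_values(["lg", "position_cM"], kind="stable").reset_index(drop=True)
    return df


# -- heuristic ordering --------------------------------------------------

def order_markers_greedy(bin_vectors: np.ndarray) -> list[int]:
    """Nearest-neighbour chaining of bins by recombination fraction.

    Starts from the pair with the smallest r (ties to the lowest bin ids)
    and repeatedly appends the unused bin with the smallest r to either end
    of the chain.  A fast stand-in for multipoint ordering, documented as a
    heuristic: output is the true order or its reversal on clean data but
    carries no optimality guarantee otherwise.
    """
    enc = np.asarray(bin_vectors, dtype=np.int8)
    m = enc.shape[0]
    if m <= 1:
        return list(range(m))
    r, _, n = _pairwise_two_point(enc)
    r = np.where(n > 0, r, np.inf)
    np.fill_diagonal(r, np.inf)
    # smallest-r pair, ties resolved by (i, j) lexicographic order
    rmin = np.min(r)
    flat = np.flatnonzero(r == rmin)
    i, j = np.unravel_index(flat[0], r.shape)
    chain = [int(min(i, j)), int(max(i, j))]
    used = set(chain)
    while len(chain) < m:
        candidates = [k for k in range(m) if k not in used]
        best_k, best_end, best_r = -1, 0, np.inf
        for k in candidates:
            for end, node in ((0, chain[0]), (1, chain[-1])):
                rk = r[k, node]
                if rk < best_r or (rk == best_r and k < best_k):
                    best_k, best_end, best_r = k, end, rk
        if best_end == 0:
            chain.insert(0, best_k)
        else:
            chain.append(best_k)
        used.add(best_k)
    return chain
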