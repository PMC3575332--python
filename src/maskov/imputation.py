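"""Convolution-based imputation and error correction of testcross genotypes.

Shallow genotyping-by-sequencing yields genotype matrices riddled with
missing calls and with isolated wrong calls that masquerade as double
recombinants, inflating map length.  Given markers already ordered within
linkage groups, each individual's phase-encoded vector over {1, 0, -1} is
cleaned in three passes:

1. *compress* — missing values (0) are removed; they carry no information
   and dilute edge detection;
2. *detect* — the zero-free vector is convolved with an antisymmetric mask
   of half-width ``E`` approximating the first derivative;
   ``conv(x_i) = sum_{k=-E..E} x_{i+k} * M_{E+k}``.  Any position where
   ``|conv| > T`` (default ``T = E``) marks a recombination edge, the sign
   of ``conv`` giving the direction of the phase transition;
3. *fill* — blocks between consecutive edges are set to their majority
   sign ("winner take all"), simultaneously correcting minority calls.

The corrected compressed vector is then expanded back to original
coordinates, each formerly-missing position inheriting its nearest
non-missing neighbour's value (ties to the left), which places inferred
crossovers at the proximal end of missing runs.

Detection/fill is iterated to a fixed point, so imputation is idempotent;
a single pass already is the fixed point on clean data.  Individuals whose
missing fraction exceeds ``max_missing`` are passed through untouched and
flagged, preserving matrix shape.

``E`` is the maximum number of expected consecutive errors.  With the sign
mask, a clean phase transition scores exactly ``2E`` while a run of ``c``
wrong calls on constant background scores ``2c``, so error runs of length
``c <= E/2`` are guaranteed to stay below the default threshold and be
corrected by the winner-take-all fill.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .model import GenotypeMatrix, decode_values, infer_phases

__all__ = [
    "MaskovParams",
    "RecombinationEdge",
    "ImputationResult",
    "ImputationOutput",
    "build_mask",
    "compress_missing",
    "convolve_genotypes",
    "detect_edges",
    "fill_blocks",
    "expand_to_original",
    "impute_individual",
    "impute_matrix",
    "MaskovImputer",
]


@dataclass(frozen=True)
class MaskovParams:
    """Tuning parameters of the imputation core.

    E:
        Half-width of the convolution mask; the maximum number of expected
        consecutive errors. Must be >= 1.
    T:
        Edge-detection threshold; an edge needs ``|conv| > T`` (strict).
        ``None`` means the default ``T = E``.
    max_missing:
        Individuals with a higher missing fraction on a linkage group are
        skipped (returned unimputed, flagged). Default 0.70.
    """

    E: int = 5
    T: float | None = None
    max_missing: float = 0.70

    def __post_init__(self) -> None:
        if int(self.E) != self.E or self.E < 1:
            raise ValueError(f"E must be an integer >= 1, got {self.E}")
        if self.T is not None and self.T <= 0:
            raise ValueError(f"T must be > 0, got {self.T}")
        if not 0.0 <= self.max_missing <= 1.0:
            raise ValueError(f"max_missing must lie in [0, 1], got {self.max_missing}")

    @property
    def threshold(self) -> float:
        return float(self.E if self.T is None else self.T)


@dataclass(frozen=True)
class RecombinationEdge:
    """A detected phase transition between two adjacent positions.

    ``left_index``/``right_index`` are the adjacent positions the edge falls
    between (compressed coordinates inside the core, original order ranks in
    results returned by :func:`impute_individual`).  ``sign`` is +1 for a
    -1 -> +1 transition, -1 for +1 -> -1; ``score`` is ``|conv|`` at the
    detection maximum.
    """

    left_index: int
    right_index: int
    sign: int
    score: float


def build_mask(E: int) -> np.ndarray:
    """Antisymmetric sign mask of length 2E+1: -1 for k<0, 0 at k=0, +1 for k>0."""
    if int(E) != E or E < 1:
        raise ValueError(f"E must be an integer >= 1, got {E}")
    return np.sign(np.arange(-E, E + 1)).astype(np.int64)


def compress_missing(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop zeros; return (values, index_map back to original positions)."""
    v = np.asarray(v)
    idx = np.flatnonzero(v)
    return v[idx].astype(np.int8), idx


def convolve_genotypes(compressed: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Convolve a zero-free genotype vector with the edge-detection mask.

    Positions whose window overruns either end (within E of a boundary) are
    set to 0 — a truncated antisymmetric window on constant input would
    score spuriously, so no edge is detectable there.
    """
    compressed = np.asarray(compressed, dtype=np.int64)
    mask = np.asarray(mask, dtype=np.int64)
    E = (len(mask) - 1) // 2
    n = len(compressed)
    out = np.zeros(n, dtype=np.int64)
    if n >= 2 * E + 1:
        # correlation: conv[i] = sum_k compressed[i+k] * mask[E+k]
        full = np.convolve(compressed, mask[::-1])
        out[E : n - E] = full[2 * E : n]
    return out


def detect_edges(convolved: np.ndarray, params: MaskovParams) -> list[RecombinationEdge]:
    """Collapse above-threshold runs of the convolved signal into edges.

    A contiguous run of positions with ``|conv| > T`` and a common sign
    yields one edge, placed between ``m`` and ``m+1`` where ``m`` is the
    leftmost position attaining the run's maximum ``|conv|`` (a clean
    transition produces a two-wide plateau at 2E, making this the exact
    breakpoint).  Adjacent runs of opposite sign yield separate edges.
    """
    conv = np.asarray(convolved)
    T = params.threshold
    edges: list[RecombinationEdge] = []
    run_start = -1
    run_sign = 0
    for i in range(len(conv) + 1):
        s = int(np.sign(conv[i])) if i < len(conv) and abs(conv[i]) > T else 0
        if s != run_sign:
            if run_sign != 0:
                seg = np.abs(conv[run_start:i])
                m = run_start + int(np.argmax(seg))
                edges.append(
                    RecombinationEdge(m, m + 1, run_sign, float(abs(conv[m])))
                )
            run_start, run_sign = i, s
    return edges


def fill_blocks(
    compressed: np.ndarray, edges: Sequence[RecombinationEdge]
) -> tuple[np.ndarray, list[RecombinationEdge]]:
    """Winner-take-all fill of the blocks delimited by the edges.

    Each block is set to the majority sign of its original values (ties go
    to the block's first entry).  Adjacent blocks that end up equal are
    merged and the separating edge dropped; surviving edges are returned
    with their sign recomputed from the filled values.
    """
    vals = np.asarray(compressed, dtype=np.int8)
    n = len(vals)
    if n == 0:
        return vals.copy(), []
    bounds = [0] + [e.right_index for e in edges] + [n]
    block_vals: list[int] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        s = int(vals[a:b].sum())
        block_vals.append(1 if s > 0 else -1 if s < 0 else int(vals[a]))
    filled = np.empty(n, dtype=np.int8)
    surviving: list[RecombinationEdge] = []
    for k, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        filled[a:b] = block_vals[k]
        if k > 0 and block_vals[k] != block_vals[k - 1]:
            e = edges[k - 1]
            surviving.append(
                RecombinationEdge(e.left_index, e.right_index, int(block_vals[k]), e.score)
            )
    return filled, surviving


def expand_to_original(
    corrected: np.ndarray, index_map: np.ndarray, original_length: int
) -> np.ndarray:
    """Expand a corrected compressed vector back to original coordinates.

    Formerly-missing positions take the value of their nearest non-missing
    neighbour (equidistant ties to the left/proximal neighbour); leading and
    trailing missing runs take the first/last corrected value.
    """
    corrected = np.asarray(corrected, dtype=np.int8)
    index_map = np.asarray(index_map, dtype=np.int64)
    if len(corrected) == 0:
        raise ValueError("cannot expand an empty corrected vector")
    pos = np.arange(original_length)
    right = np.searchsorted(index_map, pos)  # first map entry >= pos
    left = np.clip(right - 1, 0, len(index_map) - 1)
    right = np.clip(right, 0, len(index_map) - 1)
    d_left = np.abs(pos - index_map[left])
    d_right = np.abs(index_map[right] - pos)
    take_left = d_left <= d_right  # tie -> left (proximal)
    choice = np.where(take_left, left, right)
    return corrected[choice]


@dataclass
class ImputationResult:
    """Outcome of imputing one individual on one linkage group."""

    values: np.ndarray
    edges: list[RecombinationEdge]  # original order-rank coordinates
    n_missing_imputed: int = 0
    n_errors_corrected: int = 0
    n_edges: int = 0
    skipped: bool = False
    short_window: bool = False  # fewer non-missing calls than the mask width
    n_passes: int = 0


def impute_individual(v: np.ndarray, params: MaskovParams | None = None) -> ImputationResult:
    """Run the full compress -> detect -> fill -> expand pipeline on one vector.

    Detection and fill are iterated on the compressed vector until a fixed
    point is reached, so the operation is idempotent.  Vectors whose missing
    fraction exceeds ``max_missing`` (or that contain no calls at all) are
    returned unchanged and flagged ``skipped``.
    """
    params = params or MaskovParams()
    v = np.asarray(v, dtype=np.int8)
    if v.size and not np.isin(v, (-1, 0, 1)).all():
        raise ValueError("encoded vector must lie in {1, 0, -1}")
    n = len(v)
    if n == 0:
        return ImputationResult(values=v.copy(), edges=[], skipped=True)
    missing_frac = float(np.mean(v == 0))
    if missing_frac > params.max_missing:
        return ImputationResult(values=v.copy(), edges=[], skipped=True)
    vals, idx = compress_missing(v)
    if len(vals) == 0:
        return ImputationResult(values=v.copy(), edges=[], skipped=True)

    mask = build_mask(params.E)
    short = len(vals) < 2 * params.E + 1
    cur = vals
    edges: list[RecombinationEdge] = []
    n_passes = 0
    for _ in range(20):  # converges in <= 3 passes in practice
        n_passes += 1
        conv = convolve_genotypes(cur, mask)
        detected = detect_edges(conv, params)
        nxt, edges = fill_blocks(cur, detected)
        if np.array_equal(nxt, cur):
            break
        cur = nxt

    out = expand_to_original(cur, idx, n)
    orig_edges = [
        RecombinationEdge(int(idx[e.left_index]), int(idx[e.right_index]), e.sign, e.score)
        for e in edges
    ]
    return ImputationResult(
        values=out,
        edges=orig_edges,
        n_missing_imputed=int(np.sum(v == 0)),
        n_errors_corrected=int(np.sum((v != 0) & (out != v))),
        n_edges=len(orig_edges),
        skipped=False,
        short_window=short,
        n_passes=n_passes,
    )


@dataclass
class ImputationOutput:
    """Matrix-level imputation result.

    ``report`` has one row per individual x linkage group with the columns
    ``individual, lg, n_missing_imputed, n_errors_corrected, n_edges,
    skipped, pre_recombinations, post_recombinations``; ``edges`` one row
    per detected edge (``individual, lg, left_marker, right_marker, sign,
    score``).
    """

    matrix: GenotypeMatrix
    report: pd.DataFrame
    edges: pd.DataFrame

    def summary(self) -> dict:
        per_ind = self.report.groupby("individual", sort=False)[
            ["pre_recombinations", "post_recombinations"]
        ].sum()
        pre = float(per_ind["pre_recombinations"].mean())
        post = float(per_ind["post_recombinations"].mean())
        return {
            "n_missing_imputed": int(self.report["n_missing_imputed"].sum()),
            "n_errors_corrected": int(self.report["n_errors_corrected"].sum()),
            "n_edges": int(self.report["n_edges"].sum()),
            "n_skipped": int(self.report["skipped"].sum()),
            "pre_mean_recombinations": pre,
            "post_mean_recombinations": post,
        }


def _sign_changes(v: np.ndarray) -> int:
    nz = v[v != 0]
    if len(nz) < 2:
        return 0
    return int(np.sum(nz[1:] != nz[:-1]))


def impute_matrix(
    matrix: GenotypeMatrix,
    phases: np.ndarray | None = None,
    params: MaskovParams | None = None,
) -> ImputationOutput:
    """Impute every individual on every linkage group of a matrix.

    ``phases`` defaults to the matrix's own phase column when present,
    otherwise greedy phasing along the given order (:func:`infer_phases`).
    The imputed matrix is decoded back to calls under the same phases, so
    skipped individuals pass through with their missing values intact.
    """
    params = params or MaskovParams()
    matrix.check_dense_order()
    if phases is None:
        phases = matrix.phases if matrix.phases is not None else infer_phases(matrix)
    phases = np.asarray(phases, dtype=np.int8)

    from .model import encode_group  # local import to avoid cycle at module load

    new_calls = matrix.calls.copy()
    rep_rows: list[dict] = []
    edge_rows: list[dict] = []
    for g in matrix.groups():
        enc, pos, rows = encode_group(matrix, phases, g)
        order_to_row = {int(p): int(r) for p, r in zip(pos, rows)}
        for j, ind in enumerate(matrix.individual_ids):
            res = impute_individual(enc[:, j], params)
            pre = _sign_changes(enc[:, j])
            post = _sign_changes(res.values)
            rep_rows.append(
                {
                    "individual": ind,
                    "lg": g,
                    "n_missing_imputed": 0 if res.skipped else res.n_missing_imputed,
                    "n_errors_corrected": 0 if res.skipped else res.n_errors_corrected,
                    "n_edges": 0 if res.skipped else res.n_edges,
                    "skipped": res.skipped,
                    "pre_recombinations": pre,
                    "post_recombinations": post,
                }
            )
            if not res.skipped:
                new_calls[rows, j] = decode_values(res.values, phases[rows])
                for e in res.edges:
                    edge_rows.append(
                        {
                            "individual": ind,
                            "lg": g,
                            "left_marker": matrix.marker_ids[order_to_row[e.left_index]],
                            "right_marker": matrix.marker_ids[order_to_row[e.right_index]],
                            "sign": e.sign,
                            "score": e.score,
                        }
                    )
    imputed = GenotypeMatrix(
        calls=new_calls,
        marker_ids=list(matrix.marker_ids),
        linkage_group=matrix.linkage_group.copy(),
        order_index=matrix.order_index.copy(),
        individual_ids=list(matrix.individual_ids),
        phases=phases.copy(),
    )
    report = pd.DataFrame(
        rep_rows,
        columns=[
            "individual",
            "lg",
            "n_missing_imputed",
            "n_errors_corrected",
            "n_edges",
            "skipped",
            "pre_recombinations",
            "post_recombinations",
        ],
    )
    edges = pd.DataFrame(
        edge_rows,
        columns=["individual", "lg", "left_marker", "right_marker", "sign", "score"],
    )
    return ImputationOutput(matrix=imputed, report=report, edges=edges)


class MaskovImputer(TransformerMixin, BaseEstimator):
    """scikit-learn style transformer around the imputation core.

    Operates on ``(n_individuals, n_markers)`` arrays of phase-encoded
    calls over {1, 0, -1} for a *single* linkage group with markers in map
    order (samples are individuals, features are ordered markers, matching
    the sklearn samples x features convention).  ``transform`` returns the
    imputed array; rows skipped for excess missing data are passed through
    unchanged.

    Parameters mirror :class:`MaskovParams`.

    Examples
    --------
    >>> import numpy as np
    >>> X = np.array([[1, 0, 1, -1, 0, 0, -1, -1]])
    >>> MaskovImputer(E=1).fit_transform(X)
    array([[ 1,  1,  1, -1, -1, -1, -1, -1]], dtype=int8)
    """

    def __init__(self, E: int = 5, T: float | None = None, max_missing: float = 0.70):
        self.E = E
        self.T = T
        self.max_missing = max_missing

    def _params(self) -> MaskovParams:
        return MaskovParams(E=self.E, T=self.T, max_missing=self.max_missing)

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (individuals x ordered markers)")
        if X.size and not np.isin(X, (-1, 0, 1)).all():
            raise ValueError("X must be phase-encoded over {1, 0, -1}")
        return X.astype(np.int8)

    def fit(self, X, y=None):
        X = self._check_X(X)
        self._params()  # validate
        self.n_features_in_ = X.shape[1]
        self.mask_ = build_mask(self.E)
        return self

    def transform(self, X) -> np.ndarray:
        X = self._check_X(X)
        params = self._params()
        out = np.empty_like(X)
        for i in range(X.shape[0]):
            out[i] = impute_individual(X[i], params).values
        return out

    def impute(self, X) -> tuple[np.ndarray, list[list[RecombinationEdge]], pd.DataFrame]:
        """Like transform, additionally returning per-row edges and a report."""
        X = self._check_X(X)
        params = self._params()
        out = np.empty_like(X)
        edges: list[list[RecombinationEdge]] = []
        rows = []
        for i in range(X.shape[0]):
            res = impute_individual(X[i], params)
            out[i] = res.values
            edges.append(res.edges)
            rows.append(
                {
                    "row": i,
                    "n_missing_imputed": res.n_missing_imputed,
                    "n_errors_corrected": res.n_errors_corrected,
                    "n_edges": res.n_edges,
                    "skipped": res.skipped,
                }
            )
        return out, edges, pd.DataFrame(rows)
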