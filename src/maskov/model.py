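"""Domain model for pseudo-testcross (CP) genotype matrices.

In an outcrossing F1 progeny, markers heterozygous in exactly one parent
segregate 1:1 and can be mapped as a testcross for that parent.  Every cell
of a genotype matrix is one of three states: heterozygous-like, homozygous-
like, or missing.  Missing is a first-class state — genotyping-by-sequencing
data at shallow depth is dominated by it — and is never conflated with a
homozygous call.

Internally calls are small integers (``MISSING``/``HET``/``HOM``); the
surface codes of JoinMap CP files (``lm``/``ll``/``nn``/``np``/``--``) and
the simplified ``a``/``h``/``-`` alphabet are mapped onto them at I/O time.

Phase-aware encoding collapses call + phase into the signed alphabet
{1, 0, -1} used by the imputation core: a heterozygous call on a phase
``1-`` marker and a homozygous call on a phase ``0-`` marker both mean the
same parental homolog was inherited and encode as +1; the two opposite
combinations encode as -1; missing encodes as 0.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "HET",
    "HOM",
    "SegregationClass",
    "GenotypeMatrix",
    "EncodedVector",
    "MissingStats",
    "UniparentalSplit",
    "classify_segregation",
    "filter_uniparental",
    "infer_phases",
    "encode",
    "encode_group",
    "decode",
    "decode_values",
    "missing_stats",
]

# three-state call codes (np.int8 in matrices)
MISSING: int = 0
HET: int = 1
HOM: int = 2

_CALL_NAMES = {MISSING: "missing", HET: "het", HOM: "hom"}

#: surface-code dialects normalised on read; both JoinMap CP and a/h/-
DEFAULT_CODE_MAP: dict[str, int] = {
    "lm": HET,
    "np": HET,
    "ll": HOM,
    "nn": HOM,
    "h": HET,
    "a": HOM,
    "-": MISSING,
    "--": MISSING,
}


class SegregationClass(enum.Enum):
    """Parental configuration of a segregating marker.

    ``AB_X_AA``: heterozygous only in parent 1 (JoinMap ``lm x ll``);
    ``AA_X_AB``: heterozygous only in parent 2 (``nn x np``);
    ``AB_X_AB``: heterozygous in both (``hk x hk``), not usable as a
    uni-parental testcross and discarded by :func:`filter_uniparental`.
    """

    AB_X_AA = "ABxAA"
    AA_X_AB = "AAxAB"
    AB_X_AB = "ABxAB"


def _norm_zygosity(call, name: str) -> str:
    if isinstance(call, str):
        c = call.strip().lower()
        if c in ("het", "heterozygous", "ab"):
            return "het"
        if c in ("hom", "homozygous", "aa", "bb"):
            return "hom"
    elif call in (HET, HOM):
        return "het" if call == HET else "hom"
    raise ValueError(f"{name}: unknown zygosity {call!r} (expected het/hom)")


def classify_segregation(parent1_call, parent2_call) -> SegregationClass:
    """Classify a marker by which parents are heterozygous.

    Raises ``ValueError("monomorphic marker")`` when both parents are
    homozygous, because such a marker does not segregate in the progeny.
    """
    p1 = _norm_zygosity(parent1_call, "parent1")
    p2 = _norm_zygosity(parent2_call, "parent2")
    if p1 == "het" and p2 == "hom":
        return SegregationClass.AB_X_AA
    if p1 == "hom" and p2 == "het":
        return SegregationClass.AA_X_AB
    if p1 == "het" and p2 == "het":
        return SegregationClass.AB_X_AB
    raise ValueError("monomorphic marker: both parents homozygous")


@dataclass
class GenotypeMatrix:
    """Rectangular marker x individual call table with linkage-group order.

    Parameters
    ----------
    calls:
        ``(n_markers, n_individuals)`` int8 array over {MISSING, HET, HOM}.
    marker_ids:
        Unique marker names, one per row.
    linkage_group:
        Per-marker group label.
    order_index:
        Per-marker 0-based rank within its group; must be a dense
        permutation ``0..k-1`` inside every group.
    individual_ids:
        Unique progeny names, one per column.
    phases:
        Optional per-marker phase over {+1 ("1-"), -1 ("0-")}; populated by
        :func:`maskov.io.read_genotype_tsv` when the file carries a phase
        column, otherwise ``None`` (callers may use :func:`infer_phases`).
    """

    calls: np.ndarray
    marker_ids: list[str]
    linkage_group: np.ndarray
    order_index: np.ndarray
    individual_ids: list[str]
    phases: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.marker_ids = list(map(str, self.marker_ids))
        self.linkage_group = np.asarray(self.linkage_group, dtype=object)
        self.order_index = np.asarray(self.order_index, dtype=np.int64)
        self.individual_ids = list(map(str, self.individual_ids))
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D marker x individual array")
        n, m = self.calls.shape
        if len(self.marker_ids) != n:
            raise ValueError(f"{len(self.marker_ids)} marker ids for {n} rows")
        if len(self.individual_ids) != m:
            raise ValueError(f"{len(self.individual_ids)} individual ids for {m} columns")
        if len(self.linkage_group) != n or len(self.order_index) != n:
            raise ValueError("linkage_group/order_index must align with markers")
        if len(set(self.marker_ids)) != n:
            raise ValueError("duplicate marker ids")
        if len(set(self.individual_ids)) != m:
            raise ValueError("duplicate individual ids")
        bad = ~np.isin(self.calls, (MISSING, HET, HOM))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid call {self.calls[i, j]} at marker {self.marker_ids[i]!r}, "
                f"individual {self.individual_ids[j]!r}"
            )
        self.check_dense_order()
        if self.phases is not None:
            self.phases = np.asarray(self.phases, dtype=np.int8)
            if self.phases.shape != (n,) or not np.isin(self.phases, (-1, 1)).all():
                raise ValueError("phases must be per-marker values in {+1, -1}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_markers(self) -> int:
        return self.calls.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[1]

    def groups(self) -> list:
        """Group labels in order of first appearance."""
        seen: dict = {}
        for g in self.linkage_group:
            seen.setdefault(g, None)
        return list(seen)

    def check_dense_order(self) -> None:
        """Raise unless order_index is a dense 0..k-1 permutation per group."""
        for g in self.groups():
            idx = np.sort(self.order_index[self.linkage_group == g])
            if not np.array_equal(idx, np.arange(len(idx))):
                raise ValueError(
                    f"order_index within group {g!r} is not a dense permutation 0..{len(idx) - 1}"
                )

    def group_marker_indices(self, group) -> np.ndarray:
        """Row indices of a group's markers, sorted by order_index."""
        rows = np.flatnonzero(self.linkage_group == group)
        return rows[np.argsort(self.order_index[rows], kind="stable")]

    def take_markers(self, rows: Sequence[int]) -> "GenotypeMatrix":
        """Marker subset; order ranks are re-densified within each group."""
        rows = np.asarray(rows, dtype=np.int64)
        lg = self.linkage_group[rows]
        order = self.order_index[rows].astype(np.int64)
        new_order = np.empty_like(order)
        for g in dict.fromkeys(lg):
            sel = lg == g
            new_order[sel] = np.argsort(np.argsort(order[sel], kind="stable"), kind="stable")
        return GenotypeMatrix(
            calls=self.calls[rows].copy(),
            marker_ids=[self.marker_ids[i] for i in rows],
            linkage_group=lg.copy(),
            order_index=new_order,
            individual_ids=list(self.individual_ids),
            phases=None if self.phases is None else self.phases[rows].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return self.take_markers(np.arange(self.n_markers))


@dataclass
class EncodedVector:
    """One individual's ordered calls on one linkage group, phase-encoded.

    ``values`` is an int8 sequence over {1, 0, -1}; ``positions`` carries the
    original order_index of each entry.
    """

    values: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.values.shape != self.positions.shape:
            raise ValueError("values and positions must align")
        if self.values.size and not np.isin(self.values, (-1, 0, 1)).all():
            raise ValueError("encoded values must lie in {1, 0, -1}")


@dataclass
class UniparentalSplit:
    """Result of partitioning markers by segregation class."""

    parent1: GenotypeMatrix  # AB x AA markers (testcross for parent 1)
    parent2: GenotypeMatrix  # AA x AB markers (testcross for parent 2)
    n_discarded: int  # AB x AB markers dropped


@dataclass
class MissingStats:
    per_individual: np.ndarray
    per_marker: np.ndarray
    overall: float
    n_datapoints: int


def filter_uniparental(
    matrix: GenotypeMatrix, classes: Iterable[SegregationClass]
) -> UniparentalSplit:
    """Partition markers into the two uni-parental testcross matrices.

    AB x AB markers are discarded (their count is reported); the retained
    matrices get re-densified within-group order ranks.
    """
    classes = list(classes)
    if len(classes) != matrix.n_markers:
        raise ValueError("classes must align with matrix markers")
    cls = np.array([SegregationClass(c) for c in classes], dtype=object)
    rows1 = np.flatnonzero(cls == SegregationClass.AB_X_AA)
    rows2 = np.flatnonzero(cls == SegregationClass.AA_X_AB)
    n_disc = matrix.n_markers - len(rows1) - len(rows2)
    return UniparentalSplit(matrix.take_markers(rows1), matrix.take_markers(rows2), n_disc)


def missing_stats(matrix: GenotypeMatrix) -> MissingStats:
    """Per-individual / per-marker / overall missing fractions.

    The total data-point count is simply markers x individuals (323,334 for
    a 4554-marker, 71-seedling testcross matrix).
    """
    if matrix.n_markers == 0 or matrix.n_individuals == 0:
        raise ValueError("missing_stats undefined for an empty matrix")
    miss = matrix.calls == MISSING
    return MissingStats(
        per_individual=miss.mean(axis=0),
        per_marker=miss.mean(axis=1),
        overall=float(miss.mean()),
        n_datapoints=matrix.n_markers * matrix.n_individuals,
    )


# -- phase handling ------------------------------------------------------

def _encode_calls(calls: np.ndarray, phases: np.ndarray) -> np.ndarray:
    """Vectorised call+phase -> {1,0,-1}. het -> phase, hom -> -phase."""
    phases = np.asarray(phases, dtype=np.int8)
    out = np.zeros_like(calls, dtype=np.int8)
    if calls.ndim == 2:
        ph = phases[:, None]
    else:
        ph = phases
    out[calls == HET] = np.broadcast_to(ph, calls.shape)[calls == HET]
    out[calls == HOM] = -np.broadcast_to(ph, calls.shape)[calls == HOM]
    return out


def infer_phases(matrix: GenotypeMatrix) -> np.ndarray:
    """Greedy phasing along the given order within each linkage group.

    The first marker of every group is assigned phase ``1-`` (+1); each
    subsequent marker takes the phase under which its encoding agrees with
    the most recent informative marker for the majority of individuals
    (ties keep ``1-``).  This is a stand-in for phases derived from an
    external mapping run and is adequate once markers are correctly ordered:
    adjacent markers recombine rarely, so the majority vote is dominated by
    non-recombinant individuals.
    """
    phases = np.ones(matrix.n_markers, dtype=np.int8)
    for g in matrix.groups():
        rows = matrix.group_marker_indices(g)
        prev_enc: np.ndarray | None = None
        for r in rows:
            enc_plus = _encode_calls(matrix.calls[r], np.int8(1))
            if prev_enc is not None:
                agree = int(np.sum(prev_enc * enc_plus))
                phases[r] = 1 if agree >= 0 else -1
            enc = enc_plus if phases[r] == 1 else -enc_plus
            if np.any(enc != 0):
                prev_enc = enc
    return phases


def encode_group(
    matrix: GenotypeMatrix, phases: np.ndarray, group
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Encode all individuals of one linkage group at once.

    Returns ``(encoded, positions, rows)`` where ``encoded`` is an
    ``(k, n_individuals)`` int8 array with markers sorted by order_index,
    ``positions`` the order ranks, and ``rows`` the matrix row indices.
    """
    phases = np.asarray(phases, dtype=np.int8)
    if phases.shape != (matrix.n_markers,):
        raise ValueError("phases must be per-marker")
    rows = matrix.group_marker_indices(group)
    enc = _encode_calls(matrix.calls[rows], phases[rows])
    return enc, matrix.order_index[rows], rows


def encode(matrix: GenotypeMatrix, phases: np.ndarray, individual, group) -> EncodedVector:
    """Encode one individual's calls on one linkage group.

    het on a phase ``1-`` marker -> 1; hom on ``0-`` -> 1; hom on ``1-`` ->
    -1; het on ``0-`` -> -1; missing -> 0.
    """
    try:
        col = matrix.individual_ids.index(str(individual))
    except ValueError:
        raise KeyError(f"unknown individual {individual!r}") from None
    enc, pos, _ = encode_group(matrix, phases, group)
    return EncodedVector(values=enc[:, col], positions=pos)


def decode_values(values: np.ndarray, phases: np.ndarray) -> np.ndarray:
    """Inverse of the phase encoding: {1,0,-1} + phase -> call codes."""
    values = np.asarray(values, dtype=np.int8)
    phases = np.asarray(phases, dtype=np.int8)
    out = np.full(values.shape, MISSING, dtype=np.int8)
    out[values == phases] = HET
    out[(values != 0) & (values != phases)] = HOM
    return out


def decode(encoded: EncodedVector, phases: np.ndarray) -> np.ndarray:
    """Decode an :class:`EncodedVector` back to ordered call codes.

    ``phases`` must be aligned with ``encoded.values`` (one phase per
    position).  decode(encode(v)) is the identity on non-missing calls and 0
    decodes to missing.
    """
    phases = np.asarray(phases, dtype=np.int8)
    if phases.shape != encoded.values.shape:
        raise ValueError("phases must align with the encoded vector")
    return decode_values(encoded.values, phases)
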