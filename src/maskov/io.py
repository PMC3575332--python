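"""Reading and writing genotype matrices.

Two plain-text dialects are supported:

* the genotype TSV used throughout this package — header
  ``marker_id  lg  order  [phase]  <ind_1> ... <ind_n>``, one marker per
  row, ``#`` comment lines ignored, calls in either the simplified
  ``a``/``h``/``-`` alphabet or JoinMap CP codes (``lm``/``ll``/``nn``/
  ``np``/``--``), both normalised on read;
* a JoinMap CP ``.loc`` writer emitting ``<lmxll>`` / ``<nnxnp>``
  segregation types with ``lm``/``ll``/``np``/``nn``/``--`` genotypes, for
  hand-off to external mapping software.

Parse errors name the offending line.  Writes are atomic (temp file +
rename) so a crashed run never leaves a truncated matrix behind.
"""

from __future__ import annotations

import os
import tempfile
from typing import Iterable, Sequence

import numpy as np

from .model import (
    DEFAULT_CODE_MAP,
    HET,
    HOM,
    MISSING,
    GenotypeMatrix,
    SegregationClass,
)

__all__ = ["read_genotype_tsv", "write_genotype_tsv", "write_joinmap_loc", "atomic_write_text"]

_SIMPLE_CODES = {MISSING: "-", HET: "h", HOM: "a"}
_PHASE_CODES = {1: "1-", -1: "0-"}
_PHASE_PARSE = {"1-": 1, "0-": -1, "{1-}": 1, "{0-}": -1}


def atomic_write_text(path, text: str) -> None:
    """Write ``text`` to ``path`` via a temp file in the same directory."""
    path = os.fspath(path)
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", suffix=".txt")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


class ParseError(ValueError):
    """Malformed genotype file; message includes the 1-based line number."""


def read_genotype_tsv(path, code_map: dict[str, int] | None = None) -> GenotypeMatrix:
    """Read a genotype TSV into a :class:`GenotypeMatrix`.

    An optional ``phase`` column (values ``1-``/``0-``) directly after
    ``order`` is detected from the header and stored on the returned
    matrix's ``phases`` attribute.
    """
    codes = dict(DEFAULT_CODE_MAP if code_map is None else code_map)
    header: list[str] | None = None
    has_phase = False
    marker_ids: list[str] = []
    lgs: list[str] = []
    orders: list[int] = []
    phases: list[int] = []
    rows: list[list[int]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if len(header) < 4:
                    raise ParseError(f"line {lineno}: header needs marker_id, lg, order and individuals")
                if header[0] != "marker_id":
                    raise ParseError(f"line {lineno}: first header column must be 'marker_id', got {header[0]!r}")
                has_phase = len(header) > 3 and header[3] == "phase"
                continue
            meta = 4 if has_phase else 3
            if len(fields) != len(header):
                raise ParseError(
                    f"line {lineno}: expected {len(header)} fields, got {len(fields)} (ragged row)"
                )
            mid = fields[0]
            if mid in marker_ids:
                raise ParseError(f"line {lineno}: duplicate marker id {mid!r}")
            try:
                order = int(fields[2])
            except ValueError:
                raise ParseError(f"line {lineno}: order {fields[2]!r} is not an integer") from None
            if has_phase:
                ph = _PHASE_PARSE.get(fields[3].strip())
                if ph is None:
                    raise ParseError(f"line {lineno}: invalid phase code {fields[3]!r}")
                phases.append(ph)
            row = []
            for col, tok in enumerate(fields[meta:]):
                call = codes.get(tok.strip().lower())
                if call is None:
                    raise ParseError(
                        f"line {lineno}: invalid genotype code {tok!r} for marker {mid!r}, "
                        f"individual {header[meta + col]!r}"
                    )
                row.append(call)
            marker_ids.append(mid)
            lgs.append(fields[1])
            orders.append(order)
            rows.append(row)
    if header is None:
        raise ParseError("empty file: no header line found")
    meta = 4 if has_phase else 3
    individual_ids = header[meta:]
    try:
        return GenotypeMatrix(
            calls=np.array(rows, dtype=np.int8).reshape(len(rows), len(individual_ids)),
            marker_ids=marker_ids,
            linkage_group=np.array(lgs, dtype=object),
            order_index=np.array(orders, dtype=np.int64),
            individual_ids=individual_ids,
            phases=np.array(phases, dtype=np.int8) if has_phase else None,
        )
    except ValueError as exc:
        raise ParseError(str(exc)) from exc


def write_genotype_tsv(
    matrix: GenotypeMatrix,
    path,
    include_phase: bool = False,
    header_comments: Iterable[str] = (),
) -> None:
    """Write a matrix in the genotype TSV dialect (``a``/``h``/``-`` codes).

    Rows are written in the matrix's own row order (the map order lives in
    the ``order`` column, not in file position), so write -> read
    round-trips to an equal matrix.
    """
    if include_phase and matrix.phases is None:
        raise ValueError("matrix has no phases to write")
    lines = [f"# {c}" for c in header_comments]
    cols = ["marker_id", "lg", "order"] + (["phase"] if include_phase else []) + list(
        matrix.individual_ids
    )
    lines.append("\t".join(cols))
    for r in range(matrix.n_markers):
        row = [matrix.marker_ids[r], str(matrix.linkage_group[r]), str(matrix.order_index[r])]
        if include_phase:
            row.append(_PHASE_CODES[int(matrix.phases[r])])
        row.extend(_SIMPLE_CODES[int(c)] for c in matrix.calls[r])
        lines.append("\t".join(row))
    atomic_write_text(path, "\n".join(lines) + "\n")


_LOC_CODES = {
    SegregationClass.AB_X_AA: ("<lmxll>", {MISSING: "--", HET: "lm", HOM: "ll"}),
    SegregationClass.AA_X_AB: ("<nnxnp>", {MISSING: "--", HET: "np", HOM: "nn"}),
}


def write_joinmap_loc(
    matrix: GenotypeMatrix,
    classes: Sequence[SegregationClass],
    path,
    name: str = "population",
) -> None:
    """Write a JoinMap CP ``.loc`` file for the uni-parental marker classes.

    Each marker row carries its segregation type (``<lmxll>`` for AB x AA,
    ``<nnxnp>`` for AA x AB) followed by per-individual codes.  AB x AB
    markers are not representable in a single-parent testcross file and
    raise.
    """
    classes = [SegregationClass(c) for c in classes]
    if len(classes) != matrix.n_markers:
        raise ValueError("classes must align with matrix markers")
    lines = [
        f"name = {name}",
        "popt = CP",
        f"nloc = {matrix.n_markers}",
        f"nind = {matrix.n_individuals}",
        "",
    ]
    for g in matrix.groups():
        for r in matrix.group_marker_indices(g):
            cls = classes[r]
            if cls not in _LOC_CODES:
                raise ValueError(
                    f"marker {matrix.marker_ids[r]!r} is {cls.value}; only uni-parental "
                    "markers can be written to a CP testcross .loc file"
                )
            seg, table = _LOC_CODES[cls]
            codes = " ".join(table[int(c)] for c in matrix.calls[r])
            lines.append(f"{matrix.marker_ids[r]} {seg} {codes}")
    atomic_write_text(path, "\n".join(lines) + "\n")
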