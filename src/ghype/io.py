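"""Readers and writers for multigraphs and propensity matrices.

Two multigraph formats are supported:

* ``edgelist-tsv`` — UTF-8 TSV with header ``source\\ttarget\\tcount``,
  ``#``-prefixed comment lines, and one row per vertex pair.  The count
  column is optional (missing means 1); repeated rows accumulate.  Vertex
  ids are either 0-based integers or arbitrary string labels (mapped to
  indices in first-appearance order).
* ``matrix-market`` — coordinate integer Matrix Market; ``general`` for
  directed graphs, ``symmetric`` accepted for undirected.

Undirected edge lists follow the loop convention of the data model: a row
``(i, i, c)`` denotes ``c`` self-loops and is stored as ``A_ii = 2c``;
writers emit each unordered pair once (``i <= j``) with loops at their
plain multiplicity ``A_ii / 2``.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse

from ._errors import FormatError, ValidationError
from .multigraph import MultiGraph

__all__ = [
    "read_multigraph",
    "write_multigraph",
    "read_propensity",
    "write_propensity",
]

_FORMATS = ("edgelist-tsv", "matrix-market")


def _check_format(fmt: str) -> None:
    if fmt not in _FORMATS:
        raise FormatError(f"unknown format {fmt!r}; expected one of {_FORMATS}")


def read_multigraph(path: str | Path, format: str = "edgelist-tsv", *, directed: bool = True) -> MultiGraph:
    """Read a multigraph from ``path`` in the given format."""
    _check_format(format)
    path = Path(path)
    if format == "edgelist-tsv":
        return _read_edgelist(path, directed)
    return _read_matrix_market(path, directed)


def write_multigraph(g: MultiGraph, path: str | Path, format: str = "edgelist-tsv") -> None:
    """Write ``g`` to ``path``; ``read_multigraph`` round-trips bit-exactly."""
    _check_format(format)
    path = Path(path)
    if format == "edgelist-tsv":
        _write_edgelist(g, path)
    else:
        _write_matrix_market(g, path)


def _parse_count(token: str, row: int) -> int:
    try:
        value = float(token)
    except ValueError as exc:
        raise FormatError(f"row {row}: multiplicity {token!r} is not a number") from exc
    if value != int(value):
        raise FormatError(f"row {row}: multiplicity {token!r} is not an integer")
    count = int(value)
    if count < 1:
        raise FormatError(f"row {row}: multiplicity must be >= 1, got {count}")
    return count


def _read_edgelist(path: Path, directed: bool) -> MultiGraph:
    n_hint: int | None = None
    labels_hint: list[str] | None = None
    rows: list[tuple[str, str, int]] = []
    with path.open("r", encoding="utf-8") as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("n="):
                    n_hint = int(body[2:])
                elif body.startswith("labels="):
                    labels_hint = body[len("labels="):].split("\t")
                continue
            parts = line.split("\t")
            if not header_seen:
                header_seen = True
                if parts[0].strip().lower() == "source":
                    continue  # header row
            if len(parts) < 2:
                raise FormatError(f"row {lineno}: expected at least source and target columns")
            count = _parse_count(parts[2], lineno) if len(parts) >= 3 and parts[2].strip() else 1
            rows.append((parts[0].strip(), parts[1].strip(), count))

    ids = [tok for r in rows for tok in (r[0], r[1])]
    integer_ids = all(tok.isdigit() for tok in ids)
    labels: tuple[str, ...] | None
    if integer_ids and labels_hint is None:
        index = {tok: int(tok) for tok in ids}
        n = max((i + 1 for i in index.values()), default=0)
        labels = None
    else:
        order: dict[str, int] = {}
        if labels_hint is not None:
            for lab in labels_hint:
                order.setdefault(lab, len(order))
        for tok in ids:
            order.setdefault(tok, len(order))
        index = order
        n = len(order)
        labels = tuple(order)
    if n_hint is not None:
        if n_hint < n:
            raise FormatError(f"declared n={n_hint} smaller than largest vertex id ({n})")
        n = n_hint

    a = np.zeros((n, n), dtype=np.int64)
    for src, dst, count in rows:
        i, j = index[src], index[dst]
        if directed:
            a[i, j] += count
        elif i == j:
            a[i, i] += 2 * count
        else:
            a[i, j] += count
            a[j, i] += count
    return MultiGraph(counts=a, directed=directed, vertex_labels=labels)


def _write_edgelist(g: MultiGraph, path: Path) -> None:
    lines = [f"# n={g.n}"]
    if g.vertex_labels is not None:
        lines.append("# labels=" + "\t".join(g.vertex_labels))
    lines.append("source\ttarget\tcount")

    def name(i: int) -> str:
        return g.vertex_labels[i] if g.vertex_labels is not None else str(i)

    a = g.counts
    if g.directed:
        for i, j in zip(*np.nonzero(a)):
            lines.append(f"{name(i)}\t{name(j)}\t{a[i, j]}")
    else:
        for i, j in zip(*np.nonzero(np.triu(a))):
            count = a[i, j] // 2 if i == j else a[i, j]
            lines.append(f"{name(i)}\t{name(j)}\t{count}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _read_matrix_market(path: Path, directed: bool) -> MultiGraph:
    mat = scipy.io.mmread(path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat)
    if not np.issubdtype(mat.dtype, np.integer):
        if np.any(mat != np.floor(mat)):
            raise FormatError("Matrix Market multigraph must have integer entries")
        mat = mat.astype(np.int64)
    if directed is False and not np.array_equal(mat, mat.T):
        raise ValidationError("asymmetric Matrix Market input for an undirected graph")
    return MultiGraph(counts=mat, directed=directed)


def _write_matrix_market(g: MultiGraph, path: Path) -> None:
    sp = scipy.sparse.coo_matrix(g.counts)
    symmetry = "symmetric" if not g.directed else "general"
    # mmwrite appends .mtx unless the suffix is already there; write via buffer
    buf = _stdio.BytesIO()
    scipy.io.mmwrite(buf, sp, field="integer", symmetry=symmetry)
    Path(path).write_bytes(buf.getvalue())


def read_propensity(path: str | Path, format: str = "dense-tsv") -> np.ndarray:
    """Read a dense propensity matrix (``dense-tsv`` or ``matrix-market`` real)."""
    path = Path(path)
    if format == "dense-tsv":
        omega = np.loadtxt(path, delimiter="\t", dtype=float, comments="#", ndmin=2)
    elif format == "matrix-market":
        mat = scipy.io.mmread(path)
        omega = mat.toarray() if scipy.sparse.issparse(mat) else np.asarray(mat, dtype=float)
    else:
        raise FormatError(f"unknown propensity format {format!r}")
    if omega.ndim != 2 or omega.shape[0] != omega.shape[1]:
        raise FormatError(f"propensity matrix must be square, got shape {omega.shape}")
    return omega


def write_propensity(omega: np.ndarray, path: str | Path, format: str = "dense-tsv") -> None:
    path = Path(path)
    if format == "dense-tsv":
        np.savetxt(path, np.asarray(omega, dtype=float), delimiter="\t", fmt="%.17g")
    elif format == "matrix-market":
        buf = _stdio.BytesIO()
        scipy.io.mmwrite(buf, np.asarray(omega, dtype=float))
        path.write_bytes(buf.getvalue())
    else:
        raise FormatError(f"unknown propensity format {format!r}")
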