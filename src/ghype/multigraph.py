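"""Vertex-labeled multigraph data model.

A multigraph is held as a dense non-negative integer adjacency count matrix
``A`` where ``A[i, j]`` is the multiplicity of the vertex pair ``(i, j)``.
Undirected graphs follow the doubled-diagonal convention: ``A`` is symmetric
and each diagonal entry equals *twice* the multiplicity of the corresponding
self-loop, so that row sums are vertex degrees (a loop contributes 2 to the
degree of its vertex).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._errors import ValidationError

__all__ = ["MultiGraph", "DegreeSequence", "degree_sequences"]


@dataclass(frozen=True)
class MultiGraph:
    """A directed or undirected multigraph with integer edge multiplicities.

    Parameters
    ----------
    counts
        ``(n, n)`` non-negative integer matrix of pair multiplicities.
        For undirected graphs it must be symmetric with even diagonal
        (doubled-diagonal convention).
    directed
        Whether edges are directed.
    vertex_labels
        Optional string labels, one per vertex (0-based index order).
    """

    counts: np.ndarray
    directed: bool
    vertex_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.counts)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValidationError(f"adjacency counts must be square, got shape {a.shape}")
        if not np.issubdtype(a.dtype, np.integer):
            if not np.all(a == np.floor(a)):
                raise ValidationError("adjacency counts must be integers")
            a = a.astype(np.int64)
        else:
            a = a.astype(np.int64, copy=True)
        if np.any(a < 0):
            raise ValidationError("adjacency counts must be non-negative")
        if not self.directed:
            if not np.array_equal(a, a.T):
                raise ValidationError("undirected adjacency matrix must be symmetric")
            if np.any(np.diag(a) % 2 != 0):
                raise ValidationError(
                    "undirected diagonal entries must be even "
                    "(each equals twice the self-loop multiplicity)"
                )
        a.setflags(write=False)
        object.__setattr__(self, "counts", a)
        if self.vertex_labels is not None:
            labels = tuple(str(s) for s in self.vertex_labels)
            if len(labels) != a.shape[0]:
                raise ValidationError("vertex_labels length must equal vertex count")
            object.__setattr__(self, "vertex_labels", labels)

    @property
    def n(self) -> int:
        """Number of vertices."""
        return self.counts.shape[0]

    @property
    def m(self) -> int:
        """Number of (multi-)edges.

        Directed: the total of all entries.  Undirected: each unordered pair
        is counted once and each self-loop once (the doubled diagonal makes
        this the grand total divided by 2).
        """
        total = int(self.counts.sum())
        return total if self.directed else total // 2

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MultiGraph):
            return NotImplemented
        return (
            self.directed == other.directed
            and self.counts.shape == other.counts.shape
            and np.array_equal(self.counts, other.counts)
        )

    def __hash__(self) -> int:
        return hash((self.directed, self.counts.tobytes()))


@dataclass(frozen=True)
class DegreeSequence:
    """In/out degree sequences; for undirected graphs ``k_in is k_out`` (= k)."""

    k_out: np.ndarray
    k_in: np.ndarray
    directed: bool = True

    def __post_init__(self) -> None:
        ko = np.asarray(self.k_out, dtype=np.int64).copy()
        ki = np.asarray(self.k_in, dtype=np.int64).copy()
        if ko.ndim != 1 or ki.shape != ko.shape:
            raise ValidationError("degree sequences must be 1-D and of equal length")
        if np.any(ko < 0) or np.any(ki < 0):
            raise ValidationError("degrees must be non-negative")
        if self.directed:
            if ko.sum() != ki.sum():
                raise ValidationError("directed degree sequences must satisfy sum k_out == sum k_in")
        else:
            if not np.array_equal(ko, ki):
                raise ValidationError("undirected degree sequence must have k_in == k_out")
            if ko.sum() % 2 != 0:
                raise ValidationError("undirected total degree must be even")
        ko.setflags(write=False)
        ki.setflags(write=False)
        object.__setattr__(self, "k_out", ko)
        object.__setattr__(self, "k_in", ki)

    @classmethod
    def undirected(cls, k: np.ndarray) -> "DegreeSequence":
        k = np.asarray(k, dtype=np.int64)
        return cls(k_out=k, k_in=k, directed=False)

    @property
    def k(self) -> np.ndarray:
        """The (single) degree sequence of an undirected graph."""
        if self.directed:
            raise ValidationError("k is only defined for undirected degree sequences")
        return self.k_out

    @property
    def n(self) -> int:
        return self.k_out.shape[0]

    @property
    def m(self) -> int:
        """Edge count implied by the sequence (sum k_out directed, sum k / 2 undirected)."""
        s = int(self.k_out.sum())
        return s if self.directed else s // 2


def degree_sequences(g: MultiGraph) -> DegreeSequence:
    """Degree sequence(s) of a multigraph.

    Directed: ``k_out_i = sum_j A_ij`` and ``k_in_j = sum_i A_ij``.
    Undirected: ``k_i = sum_j A_ij`` — the doubled diagonal makes every
    self-loop contribute 2, as required.
    """
    k_out = g.counts.sum(axis=1)
    k_in = g.counts.sum(axis=0)
    return DegreeSequence(k_out=k_out, k_in=k_in, directed=g.directed)
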