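"""District contiguity structures, GAL I/O, and Moran's I.

A :class:`SpatialWeights` holds the binary symmetric border-sharing
matrix W over an ordered list of district labels (w_ij = 1 iff districts
i and j share a border), together with the neighbour counts w_j+ that
the Leroux CAR prior needs. Moran's I is computed with either binary or
row-standardised weights and permutation inference (exhaustive when the
number of districts is small enough to enumerate).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SpatialWeights",
    "MoranResult",
    "weights_from_edges",
    "rook_lattice",
    "read_gal",
    "write_gal",
    "morans_i",
]


@dataclass(frozen=True)
class SpatialWeights:
    """Binary contiguity matrix over an ordered set of district labels."""

    district_ids: tuple[str, ...]
    matrix: np.ndarray  # J x J, symmetric, zero diagonal, {0, 1}

    def __post_init__(self) -> None:
        ids = tuple(str(d) for d in self.district_ids)
        object.__setattr__(self, "district_ids", ids)
        W = np.asarray(self.matrix, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weight matrix must be square")
        if W.shape[0] != len(ids):
            raise ValueError("matrix size does not match number of districts")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate district labels")
        if not np.array_equal(W, W.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("weight matrix must have a zero diagonal")
        if not np.isin(W, (0.0, 1.0)).all():
            raise ValueError("weight matrix entries must be 0 or 1")
        W = W.copy()
        W.flags.writeable = False
        object.__setattr__(self, "matrix", W)

    @property
    def n_districts(self) -> int:
        return len(self.district_ids)

    @property
    def neighbor_counts(self) -> np.ndarray:
        """w_j+ : number of districts sharing a border with district j."""
        return self.matrix.sum(axis=1)

    @property
    def islands(self) -> tuple[str, ...]:
        return tuple(
            d for d, c in zip(self.district_ids, self.neighbor_counts) if c == 0
        )

    def index_of(self, label: str) -> int:
        try:
            return self.district_ids.index(str(label))
        except ValueError:
            raise KeyError(f"unknown district label {label!r}") from None

    def edges(self) -> list[tuple[str, str]]:
        i, j = np.nonzero(np.triu(self.matrix))
        return [(self.district_ids[a], self.district_ids[b]) for a, b in zip(i, j)]


def weights_from_edges(
    edges: Iterable[tuple[str, str]], districts: Sequence[str]
) -> SpatialWeights:
    """Build a symmetric binary W from an (unordered) edge list.

    Edge orientation is irrelevant and duplicates collapse; self-edges and
    labels not in ``districts`` are errors.
    """
    ids = [str(d) for d in districts]
    pos = {d: k for k, d in enumerate(ids)}
    W = np.zeros((len(ids), len(ids)))
    for a, b in edges:
        a, b = str(a), str(b)
        if a not in pos or b not in pos:
            unknown = a if a not in pos else b
            raise KeyError(f"edge endpoint {unknown!r} is not a known district")
        if a == b:
            raise ValueError(f"self-edge at district {a!r}")
        W[pos[a], pos[b]] = 1.0
        W[pos[b], pos[a]] = 1.0
    return SpatialWeights(tuple(ids), W)


def rook_lattice(
    nrows: int, ncols: int, labels: Sequence[str] | None = None, n_islands: int = 0
) -> SpatialWeights:
    """Rook-contiguity lattice of nrows x ncols cells plus optional islands.

    The islands (isolated districts with no neighbours, like Likoma in the
    Malawi district map) are appended after the lattice cells.
    """
    n = nrows * ncols + n_islands
    if labels is None:
        labels = [f"D{k + 1:02d}" for k in range(n)]
    if len(labels) != n:
        raise ValueError("label count must equal nrows*ncols + n_islands")
    edges = []
    for r in range(nrows):
        for c in range(ncols):
            k = r * ncols + c
            if c + 1 < ncols:
                edges.append((labels[k], labels[k + 1]))
            if r + 1 < nrows:
                edges.append((labels[k], labels[k + ncols]))
    return weights_from_edges(edges, labels)


def read_gal(path: str | Path) -> SpatialWeights:
    """Read a GAL neighbour-list file (GeoDa dialect).

    Header is either ``J`` or ``0 J <name> <key>``; each record is a line
    ``label n_neighbors`` followed by a line of neighbour labels.
    Asymmetric listings are symmetrised with a warning.
    """
    lines = [
        ln
        for ln in Path(path).read_text().splitlines()
        if not ln.lstrip().startswith("#")
    ]
    while lines and not lines[0].strip():
        lines = lines[1:]
    if not lines:
        raise ValueError("empty GAL file")
    head = lines[0].split()
    try:
        n = int(head[1]) if len(head) > 1 and head[0] == "0" else int(head[0])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"malformed GAL header {lines[0]!r}") from exc
    # records are whitespace-tokenizable: label count n1 ... n_count, with
    # line breaks (including the blank line of a zero-neighbour record) free
    tokens = " ".join(lines[1:]).split()
    ids: list[str] = []
    neigh: dict[str, list[str]] = {}
    pos_t = 0
    for _ in range(n):
        if pos_t + 2 > len(tokens) + 1:
            raise ValueError("GAL file truncated")
        try:
            label, cnt = tokens[pos_t], int(tokens[pos_t + 1])
        except (IndexError, ValueError) as exc:
            raise ValueError(
                f"malformed GAL record near token {pos_t}: {tokens[pos_t:pos_t + 2]}"
            ) from exc
        nbrs = tokens[pos_t + 2 : pos_t + 2 + cnt]
        if len(nbrs) != cnt:
            raise ValueError(
                f"district {label!r}: listed {len(nbrs)} neighbours, header says {cnt}"
            )
        pos_t += 2 + cnt
        ids.append(label)
        neigh[label] = nbrs
    if pos_t != len(tokens):
        raise ValueError("trailing data after GAL records")
    pos = {d: k for k, d in enumerate(ids)}
    W = np.zeros((n, n))
    for d, nbrs in neigh.items():
        for b in nbrs:
            if b not in pos:
                raise ValueError(f"district {d!r} lists unknown neighbour {b!r}")
            W[pos[d], pos[b]] = 1.0
    if not np.array_equal(W, W.T):
        warnings.warn(
            "GAL file lists some neighbour pairs one-directionally; symmetrising",
            stacklevel=2,
        )
        W = np.maximum(W, W.T)
    np.fill_diagonal(W, 0.0)
    return SpatialWeights(tuple(ids), W)


def write_gal(weights: SpatialWeights, path: str | Path) -> None:
    """Write canonical GAL: ``J`` header, then per-district record pairs."""
    out = [str(weights.n_districts)]
    W = weights.matrix
    for k, d in enumerate(weights.district_ids):
        nbrs = [weights.district_ids[j] for j in np.nonzero(W[k])[0]]
        out.append(f"{d} {len(nbrs)}")
        out.append(" ".join(nbrs))
    Path(path).write_text("\n".join(out) + "\n")


@dataclass(frozen=True)
class MoranResult:
    """Global Moran's I with permutation inference."""

    I: float
    expected_I: float
    p_value: float
    n_permutations: int
    standardization: str
    exact: bool = False
    permutation_mean: float = field(default=math.nan)


def _moran_stat(x: np.ndarray, W: np.ndarray, S0: float) -> float:
    z = x - x.mean()
    denom = float(z @ z)
    return len(x) / S0 * float(z @ W @ z) / denom


def morans_i(
    values: Sequence[float] | np.ndarray,
    weights: SpatialWeights,
    standardization: str = "row",
    n_permutations: int = 9999,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> MoranResult:
    """Moran's I for a per-district variable with permutation inference.

    I = (J / S0) * sum_ij w*_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2,
    with w* the binary or row-standardised weights and S0 = sum_ij w*_ij.
    Islands are dropped (with a warning) before computing; the permutation
    p-value uses the +1 correction, or exhaustive enumeration of all J!
    relabelings when that is cheaper than the requested permutation count.
    """
    x = np.asarray(values, dtype=float)
    if x.shape != (weights.n_districts,):
        raise ValueError("values must align with weights.district_ids")
    keep = weights.neighbor_counts > 0
    if not keep.any():
        raise ValueError("all districts are islands; Moran's I undefined")
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} island district(s) from Moran's I",
            stacklevel=2,
        )
        x = x[keep]
    W = weights.matrix[np.ix_(keep, keep)]
    if np.ptp(x) == 0:
        raise ValueError("values are constant; Moran's I undefined")
    if standardization == "row":
        rs = W.sum(axis=1, keepdims=True)
        W = W / rs
    elif standardization != "binary":
        raise ValueError("standardization must be 'row' or 'binary'")
    S0 = float(W.sum())
    J = len(x)
    expected = -1.0 / (J - 1)
    I_obs = _moran_stat(x, W, S0)

    exact = math.factorial(J) <= max(n_permutations, 40320)
    if exact:
        perms = np.array(list(permutations(range(J))))
        stats = np.array([_moran_stat(x[p], W, S0) for p in perms])
        n_used = len(stats)
        extreme = _count_extreme(stats, I_obs, expected, alternative)
        p = extreme / n_used
    else:
        rng = np.random.default_rng(seed)
        stats = np.empty(n_permutations)
        for k in range(n_permutations):
            stats[k] = _moran_stat(rng.permutation(x), W, S0)
        n_used = n_permutations
        extreme = _count_extreme(stats, I_obs, expected, alternative)
        p = (extreme + 1) / (n_used + 1)
    return MoranResult(
        I=I_obs,
        expected_I=expected,
        p_value=float(min(p, 1.0)),
        n_permutations=n_used,
        standardization=standardization,
        exact=exact,
        permutation_mean=float(stats.mean()),
    )


def _count_extreme(
    stats: np.ndarray, I_obs: float, expected: float, alternative: str
) -> int:
    tol = 1e-12  # ties at the observed statistic count as extreme
    if alternative == "two-sided":
        return int((np.abs(stats - expected) >= abs(I_obs - expected) - tol).sum())
    if alternative == "greater":
        return int((stats >= I_obs - tol).sum())
    if alternative == "less":
        return int((stats <= I_obs + tol).sum())
    raise ValueError("alternative must be 'two-sided', 'greater' or 'less'")
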