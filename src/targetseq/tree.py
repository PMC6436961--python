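"""Mutation-tree inference under a false-positive / allelic-dropout model.

The model: a rooted tree over ``m`` mutation nodes (plus an implicit
wild-type root) defines, for each possible attachment node, the expected
binary genotype (mutations on the root path are 1).  An observed cell
genotype deviates from the expectation with false-discovery probability
``fd`` (0 observed as 1) and allelic-dropout probability ``ad`` (1 observed
as 0); missing entries contribute nothing.  A cell's marginal likelihood
averages over all ``m+1`` attachments with a uniform prior, and the tree
score is the summed log marginal over cells.  Loss of heterozygosity is
handled upstream by encoding each allele of an affected variant as its own
binary character.

Inference is exact for small panels (all ``(m+1)^(m-1)`` rooted labeled
trees via Pruefer-sequence enumeration, feasible to ``m = 7``) and a seeded
steepest-ascent prune-and-reattach search with restarts beyond that.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .panel import ConfigurationError

__all__ = [
    "ErrorRates",
    "MutationTree",
    "encode_matrix",
    "tree_loglik",
    "infer_tree",
    "mutation_order",
    "enumerate_trees",
    "read_matrix_tsv",
    "write_matrix_tsv",
]


@dataclass(frozen=True)
class ErrorRates:
    """fd = P(observe 1 | true 0); ad = P(observe 0 | true 1)."""

    fd: float = 0.001
    ad: float = 0.01

    def __post_init__(self) -> None:
        for name, v in (("fd", self.fd), ("ad", self.ad)):
            if not (0 <= v < 0.5):
                raise ConfigurationError(f"{name} must be in [0, 0.5), got {v}")


@dataclass(frozen=True)
class MutationTree:
    """Rooted mutation tree as a parent vector.

    ``parents[i]`` is the parent of character ``i``; the value ``m``
    (``len(parents)``) denotes the implicit wild-type root.
    """

    parents: tuple[int, ...]
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        m = len(self.parents)
        names = self.names or tuple(f"M{i}" for i in range(m))
        object.__setattr__(self, "names", tuple(names))
        if len(self.names) != m:
            raise ConfigurationError("names length must match parent vector")
        for i, p in enumerate(self.parents):
            if not (0 <= p <= m) or p == i:
                raise ConfigurationError(f"invalid parent {p} for node {i}")
        # acyclicity: every node must reach the root
        for i in range(m):
            seen = set()
            j = i
            while j != m:
                if j in seen:
                    raise ConfigurationError("parent vector contains a cycle")
                seen.add(j)
                j = self.parents[j]

    @property
    def m(self) -> int:
        return len(self.parents)

    def root_path(self, node: int) -> list[int]:
        """Characters on the path from the root down to ``node`` (inclusive)."""
        path = []
        j = node
        while j != self.m:
            path.append(j)
            j = self.parents[j]
        return path[::-1]

    def attachment_genotypes(self) -> np.ndarray:
        """(m+1) x m binary matrix of expected genotypes per attachment node.

        Row ``m`` is the root (all zero).
        """
        m = self.m
        E = np.zeros((m + 1, m), dtype=float)
        for v in range(m):
            E[v, self.root_path(v)] = 1.0
        return E

    def children(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {i: [] for i in range(self.m + 1)}
        for i, p in enumerate(self.parents):
            ch[p].append(i)
        return ch

    def is_ancestor(self, a: int, b: int) -> bool:
        """True if character ``a`` lies on the root path of ``b`` (a != b)."""
        j = self.parents[b]
        while j != self.m:
            if j == a:
                return True
            j = self.parents[j]
        return False

    def newick(self) -> str:
        ch = self.children()

        def sub(node: int) -> str:
            kids = ch[node]
            label = "root" if node == self.m else self.names[node]
            if not kids:
                return label
            return "(" + ",".join(sub(k) for k in kids) + ")" + label

        return sub(self.m) + ";"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"parents": list(self.parents), "names": list(self.names)})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "MutationTree":
        d = json.loads(Path(path).read_text())
        return cls(parents=tuple(d["parents"]), names=tuple(d["names"]))


# ---------------------------------------------------------------------------
# encoding


_ENCODE_PLAIN = {"WT": 0.0, "HET": 1.0, "HOM": 1.0}
_ENCODE_LOH = {"WT": (0.0, 0.0), "HET": (1.0, 0.0), "HOM": (1.0, 1.0)}


def encode_matrix(
    calls: pd.DataFrame, loh_variants: Sequence[str] = ()
) -> pd.DataFrame:
    """Encode integrated genotype calls as binary characters with missing.

    Non-LOH variants map WT to 0, HET/HOM to 1, anything else to missing
    (NaN).  Variants listed in ``loh_variants`` are split into two allele
    characters (``<name>.a1``/``<name>.a2``): WT is (0,0), HET (1,0),
    HOM (1,1), so loss of heterozygosity becomes a second acquisition
    event on the tree.
    """
    missing = set(loh_variants) - set(calls.columns)
    if missing:
        raise ConfigurationError(f"LOH variants absent from matrix: {sorted(missing)}")
    out: dict[str, list[float]] = {}
    for v in calls.columns:
        col = calls[v]
        if v in loh_variants:
            pairs = [_ENCODE_LOH.get(c, (np.nan, np.nan)) for c in col]
            out[f"{v}.a1"] = [p[0] for p in pairs]
            out[f"{v}.a2"] = [p[1] for p in pairs]
        else:
            out[v] = [_ENCODE_PLAIN.get(c, np.nan) for c in col]
    return pd.DataFrame(out, index=calls.index)


# ---------------------------------------------------------------------------
# likelihood


def _as_array(mm: pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(mm, pd.DataFrame):
        return mm.to_numpy(dtype=float)
    return np.asarray(mm, dtype=float)


_LOG_FLOOR = -1e300  # stands in for log(0); keeps 0 * log(0) = 0 in matmuls


def _log_factors(er: ErrorRates) -> tuple[float, float, float, float]:
    with np.errstate(divide="ignore"):
        logs = np.log([er.fd, 1 - er.fd, er.ad, 1 - er.ad])
    l_fd, l_nfd, l_ad, l_nad = np.maximum(logs, _LOG_FLOOR)
    return float(l_fd), float(l_nfd), float(l_ad), float(l_nad)


def _attachment_loglik(obs: np.ndarray, E: np.ndarray, er: ErrorRates) -> np.ndarray:
    """n_cells x (m+1) log P(cell | attachment) under the error model."""
    O1 = (obs == 1).astype(float)  # NaN (missing) compares False -> factor 1
    O0 = (obs == 0).astype(float)
    l_fd, l_nfd, l_ad, l_nad = _log_factors(er)
    Et = E.T  # characters x attachments
    W1 = np.where(Et == 1, l_nad, l_fd)  # log P(observe 1 | expected)
    W0 = np.where(Et == 1, l_ad, l_nfd)  # log P(observe 0 | expected)
    return O1 @ W1 + O0 @ W0


def tree_loglik(
    mm: pd.DataFrame | np.ndarray, tree: MutationTree, er: ErrorRates = ErrorRates()
) -> float:
    """Log-likelihood of a mutation matrix given a tree and error rates.

    Each cell contributes the log of its attachment-averaged likelihood
    (uniform prior over the ``m+1`` nodes including the root); missing
    entries contribute a factor of 1.  Computed in log space.
    """
    obs = _as_array(mm)
    if obs.shape[1] != tree.m:
        raise ConfigurationError(
            f"matrix has {obs.shape[1]} characters but tree has {tree.m}"
        )
    ll = _attachment_loglik(obs, tree.attachment_genotypes(), er)
    marg = logsumexp(ll, axis=1) - np.log(tree.m + 1)
    return float(marg.sum())


def cell_attachment_posteriors(
    mm: pd.DataFrame | np.ndarray, tree: MutationTree, er: ErrorRates = ErrorRates()
) -> np.ndarray:
    """Per-cell posterior over attachment nodes (columns; last is root)."""
    ll = _attachment_loglik(_as_array(mm), tree.attachment_genotypes(), er)
    ll -= logsumexp(ll, axis=1, keepdims=True)
    return np.exp(ll)


# ---------------------------------------------------------------------------
# enumeration and search


def _pruefer_to_parents(seq: Sequence[int], m: int) -> tuple[int, ...]:
    """Decode a Pruefer sequence over m+1 labels into a parent vector rooted at m."""
    import heapq

    n = m + 1
    degree = [1] * n
    for x in seq:
        degree[x] += 1
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    leaves = [i for i in range(n) if degree[i] == 1]
    heapq.heapify(leaves)
    edges = []
    for x in seq:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, x))
        degree[x] -= 1
        if degree[x] == 1:
            heapq.heappush(leaves, x)
    u = heapq.heappop(leaves)
    v = heapq.heappop(leaves)
    edges.append((u, v))
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    # root at m, derive parents by BFS
    parents = [m] * m
    stack = [m]
    seen = {m}
    while stack:
        node = stack.pop()
        for nb in adj[node]:
            if nb not in seen:
                seen.add(nb)
                if nb != m:
                    parents[nb] = node
                stack.append(nb)
    return tuple(parents)


def enumerate_trees(m: int, names: Sequence[str] = ()) -> Iterable[MutationTree]:
    """All rooted labeled mutation trees on m characters ((m+1)^(m-1) of them)."""
    if m == 1:
        yield MutationTree(parents=(1,), names=tuple(names) or ("M0",))
        return
    names = tuple(names) or tuple(f"M{i}" for i in range(m))
    for seq in itertools.product(range(m + 1), repeat=m - 1):
        yield MutationTree(parents=_pruefer_to_parents(seq, m), names=names)


def _random_tree(m: int, rng: np.random.Generator, names: Sequence[str]) -> MutationTree:
    seq = tuple(rng.integers(0, m + 1, size=max(m - 1, 0)))
    if m == 1:
        return MutationTree(parents=(1,), names=tuple(names))
    return MutationTree(parents=_pruefer_to_parents(seq, m), names=tuple(names))


def _neighbors(tree: MutationTree) -> Iterable[MutationTree]:
    """Prune-and-reattach plus node-label swap moves."""
    m = tree.m
    for i in range(m):
        for p in range(m + 1):
            if p == tree.parents[i] or p == i:
                continue
            if p != m and tree.is_ancestor(i, p):
                continue  # would create a cycle
            parents = list(tree.parents)
            parents[i] = p
            yield MutationTree(parents=tuple(parents), names=tree.names)
    for i in range(m):
        for j in range(i + 1, m):
            # exchange the tree positions of characters i and j
            relabel = {i: j, j: i}
            parents = [0] * m
            for k in range(m):
                src = relabel.get(k, k)
                p = tree.parents[src]
                parents[k] = relabel.get(p, p)
            if parents[i] != i and parents[j] != j:
                yield MutationTree(parents=tuple(parents), names=tree.names)


_TIE_TOL = 1e-9


def infer_tree(
    mm: pd.DataFrame | np.ndarray,
    er: ErrorRates = ErrorRates(),
    mode: str = "exhaustive",
    seed: int = 0,
    restarts: int = 1,
) -> tuple[list[MutationTree], float]:
    """Maximum-likelihood mutation tree(s) for a genotype matrix.

    ``exhaustive`` enumerates every rooted labeled tree (requires
    ``m <= 7``); ``search`` runs a seeded steepest-ascent hill climb over
    prune-and-reattach moves with ``restarts`` random restarts (the
    single-repetition default mirrors the error-model tree search this
    re-implements).  Co-optimal trees (within 1e-9 log units) are all
    returned, ordered lexicographically by parent vector.
    """
    obs = _as_array(mm)
    m = obs.shape[1]
    names = tuple(mm.columns) if isinstance(mm, pd.DataFrame) else tuple(f"M{i}" for i in range(m))

    if mode == "exhaustive":
        if m > 7:
            raise ConfigurationError(
                f"exhaustive enumeration limited to m <= 7 (got {m}); use mode='search'"
            )
        best: list[MutationTree] = []
        best_ll = -np.inf
        for t in enumerate_trees(m, names):
            ll = tree_loglik(obs, t, er)
            if ll > best_ll + _TIE_TOL:
                best, best_ll = [t], ll
            elif ll >= best_ll - _TIE_TOL:
                best.append(t)
        best.sort(key=lambda t: t.parents)
        return best, best_ll

    if mode != "search":
        raise ConfigurationError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed)
    best: list[MutationTree] = []
    best_ll = -np.inf
    for _ in range(restarts):
        current = _random_tree(m, rng, names)
        current_ll = tree_loglik(obs, current, er)
        improved = True
        while improved:
            improved = False
            step_best, step_ll = None, current_ll
            for nb in _neighbors(current):
                ll = tree_loglik(obs, nb, er)
                if ll > step_ll + _TIE_TOL:
                    step_best, step_ll = nb, ll
            if step_best is not None:
                current, current_ll = step_best, step_ll
                improved = True
        if current_ll > best_ll + _TIE_TOL:
            best, best_ll = [current], current_ll
        elif current_ll >= best_ll - _TIE_TOL and current.parents not in {
            t.parents for t in best
        }:
            best.append(current)
    # collect co-optimal neighbors at the summit for deterministic ties
    best.sort(key=lambda t: t.parents)
    return best, best_ll


def mutation_order(tree: MutationTree) -> dict[str, list[tuple[str, str]]]:
    """Mutation acquisition order implied by a tree.

    Returns ``ordered`` — all (earlier, later) ancestor pairs — and
    ``independent`` — pairs on different branches, i.e. mutations acquired
    independently with no implied order.
    """
    ordered: list[tuple[str, str]] = []
    independent: list[tuple[str, str]] = []
    for a in range(tree.m):
        for b in range(tree.m):
            if a == b:
                continue
            if tree.is_ancestor(a, b):
                ordered.append((tree.names[a], tree.names[b]))
    for a in range(tree.m):
        for b in range(a + 1, tree.m):
            if not tree.is_ancestor(a, b) and not tree.is_ancestor(b, a):
                independent.append((tree.names[a], tree.names[b]))
    return {"ordered": ordered, "independent": independent}


def write_matrix_tsv(mm: pd.DataFrame, path: str | Path) -> None:
    mm.to_csv(path, sep="\t", index_label="cell_id", na_rep="NA")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="cell_id", na_values="NA")
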