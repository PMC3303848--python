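"""Closed-form Bayesian scoring of DAG structures on complete discrete data.

For a Bayesian network structure ``G`` over multinomial variables with a
Dirichlet parameter prior, the marginal likelihood ``P(D|G)`` factorizes
over families (a child and its parent set).  With ``N_ijk`` the number of
rows where child ``i`` takes state ``k`` under the ``j``-th parent
configuration, and ``a_ijk`` the Dirichlet hyperparameters,

    log P(D|G) = sum_i sum_j [ lnG(a_ij) - lnG(a_ij + N_ij)
                               + sum_k ( lnG(a_ijk + N_ijk) - lnG(a_ijk) ) ]

where ``a_ij = sum_k a_ijk`` and ``lnG`` is the log-gamma function.  Two
hyperparameter schemes are offered:

* ``CH`` — every ``a_ijk = 1`` (the classical uniform-parameter closed
  form).  This is the default.
* ``BDeu`` — ``a_ijk = ess / (r_i * q_i)`` for an equivalent sample size
  ``ess``, giving likelihood score-equivalence across Markov-equivalent
  DAGs.

The structure prior is uniform over DAGs respecting the parent limit, so
it contributes only an additive constant and is omitted from scores;
posterior ratios between structures equal exponentiated score differences.

All arithmetic is in the log domain via log-gamma; for the CH prior the
integer log-gamma values are precomputed into a lookup table once per
dataset, which makes a family evaluation a couple of fancy-indexing sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "DAGStructure",
    "ScoreConfig",
    "FamilyCountCache",
    "family_log_marginal",
    "dag_log_score",
    "score_delta",
]


class DAGStructure:
    """A directed acyclic graph over dataset variables; the MCMC state.

    Thin wrapper around a boolean adjacency matrix (``adj[u, v]`` means an
    edge ``u -> v``).  Mutating helpers do not re-check acyclicity; callers
    (the sampler, the enumerator) maintain that invariant and tests assert
    it via :meth:`is_acyclic`.
    """

    __slots__ = ("n_vars", "adj")

    def __init__(self, n_vars: int, adj: np.ndarray | None = None):
        self.n_vars = n_vars
        if adj is None:
            adj = np.zeros((n_vars, n_vars), dtype=bool)
        else:
            adj = np.array(adj, dtype=bool)
            if adj.shape != (n_vars, n_vars):
                raise ValueError("adjacency shape mismatch")
            if adj.diagonal().any():
                raise ValueError("self-loops not allowed")
        self.adj = adj

    @classmethod
    def from_edges(cls, n_vars: int, edges: Iterable[tuple[int, int]]) -> "DAGStructure":
        g = cls(n_vars)
        for u, v in edges:
            g.adj[u, v] = True
        if not g.is_acyclic():
            raise ValueError("edge list contains a cycle")
        return g

    def copy(self) -> "DAGStructure":
        return DAGStructure(self.n_vars, self.adj.copy())

    def parents(self, v: int) -> tuple[int, ...]:
        return tuple(np.flatnonzero(self.adj[:, v]))

    @property
    def parent_sets(self) -> list[tuple[int, ...]]:
        return [self.parents(v) for v in range(self.n_vars)]

    def children(self, v: int) -> tuple[int, ...]:
        return tuple(np.flatnonzero(self.adj[v, :]))

    def has_edge(self, u: int, v: int) -> bool:
        return bool(self.adj[u, v])

    def edges(self) -> list[tuple[int, int]]:
        return [tuple(e) for e in np.argwhere(self.adj)]

    @property
    def n_edges(self) -> int:
        return int(self.adj.sum())

    def apply_move(self, move: tuple[str, int, int]) -> None:
        op, u, v = move
        if op == "add":
            if self.adj[u, v]:
                raise ValueError(f"edge {u}->{v} already present")
            self.adj[u, v] = True
        elif op == "delete":
            if not self.adj[u, v]:
                raise ValueError(f"edge {u}->{v} not present")
            self.adj[u, v] = False
        elif op == "reverse":
            if not self.adj[u, v]:
                raise ValueError(f"edge {u}->{v} not present")
            self.adj[u, v] = False
            self.adj[v, u] = True
        else:
            raise ValueError(f"unknown operator {op!r}")

    def is_acyclic(self) -> bool:
        # Kahn's algorithm on the small adjacency matrix.
        adj = self.adj.copy()
        indeg = adj.sum(axis=0)
        active = np.ones(self.n_vars, dtype=bool)
        for _ in range(self.n_vars):
            free = np.flatnonzero(active & (indeg == 0))
            if free.size == 0:
                return not active.any()
            for u in free:
                indeg -= adj[u, :]
                adj[u, :] = False
                active[u] = False
        return not active.any()

    def __eq__(self, other):
        return isinstance(other, DAGStructure) and np.array_equal(self.adj, other.adj)

    def __hash__(self):
        return hash(self.adj.tobytes())

    def __repr__(self):
        return f"DAGStructure(n_vars={self.n_vars}, edges={self.edges()})"


@dataclass(frozen=True)
class ScoreConfig:
    """Prior configuration for the family score.

    ``max_parents`` caps parent-set sizes (default 8), which restricts —
    and thereby implicitly reshapes — the uniform structure prior.
    """

    prior_kind: str = "CH"
    ess: float = 1.0
    max_parents: int = 8
    structure_prior: str = "uniform"

    def __post_init__(self):
        if self.prior_kind not in ("CH", "BDeu"):
            raise ValueError(f"unknown prior {self.prior_kind!r}")
        if self.prior_kind == "BDeu" and not self.ess > 0:
            raise ValueError("BDeu requires ess > 0")
        if self.structure_prior != "uniform":
            raise ValueError("only the uniform structure prior is supported")


class FamilyCountCache:
    """Sufficient statistics and cached family log-scores for one dataset.

    Keyed by ``(child, sorted parent tuple)``.  The cache is exact: a hit
    returns precisely what recomputation from data would.
    """

    def __init__(self, dataset, cfg: ScoreConfig | None = None):
        from .data_model import DiscreteDataset

        self.cfg = cfg or ScoreConfig()
        if isinstance(dataset, DiscreteDataset):
            dataset.require_complete()
            codes = dataset.codes
            arities = dataset.arities
        else:  # raw (codes, arities) pair, used by tests and the oracle
            codes, arities = dataset
            codes = np.asarray(codes)
            arities = np.asarray(arities, dtype=np.int64)
        self.n_rows, self.n_vars = codes.shape
        self.arity = arities
        self.cols = [np.ascontiguousarray(codes[:, j], dtype=np.int64)
                     for j in range(self.n_vars)]
        # integer log-gamma table for the CH prior; index t -> lnGamma(t)
        max_idx = self.n_rows + int(arities.max(initial=2)) + 2
        self._gl = gammaln(np.arange(max_idx + 1, dtype=np.float64))
        self._cache: dict[tuple, float] = {}

    def counts(self, child: int, parents: Sequence[int]) -> np.ndarray:
        """N_ijk matrix of shape (q, r): parent configurations x child states."""
        r = int(self.arity[child])
        if len(parents) == 0:
            n = np.bincount(self.cols[child], minlength=r)
            return n.reshape(1, r)
        idx = np.zeros(self.n_rows, dtype=np.int64)
        q = 1
        for p in parents:
            idx = idx * self.arity[p] + self.cols[p]
            q *= int(self.arity[p])
        joint = idx * r + self.cols[child]
        return np.bincount(joint, minlength=q * r).reshape(q, r)

    def family_score(self, child: int, parents: Sequence[int]) -> float:
        parents = tuple(sorted(parents))
        if child in parents:
            raise ValueError("child cannot be its own parent")
        if len(parents) > self.cfg.max_parents:
            raise ValueError(
                f"parent set of size {len(parents)} exceeds limit "
                f"{self.cfg.max_parents}"
            )
        key = (child, parents)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        n = self.counts(child, parents)
        r = int(self.arity[child])
        q = n.shape[0]
        if self.cfg.prior_kind == "CH":
            gl = self._gl
            row_tot = n.sum(axis=1)
            val = float(q * gl[r] - gl[row_tot + r].sum() + gl[n + 1].sum())
        else:  # BDeu
            a_ij = self.cfg.ess / q
            a_ijk = self.cfg.ess / (q * r)
            row_tot = n.sum(axis=1)
            val = float(
                q * gammaln(a_ij)
                - gammaln(row_tot + a_ij).sum()
                + gammaln(n + a_ijk).sum()
                - q * r * gammaln(a_ijk)
            )
        self._cache[key] = val
        return val

    def __len__(self):
        return len(self._cache)


def family_log_marginal(child, parents, data, cfg: ScoreConfig | None = None,
                        cache: FamilyCountCache | None = None) -> float:
    """Log marginal likelihood contribution of one family."""
    if cache is None:
        cache = FamilyCountCache(data, cfg)
    return cache.family_score(child, parents)


def dag_log_score(g: DAGStructure, data, cfg: ScoreConfig | None = None,
                  cache: FamilyCountCache | None = None) -> float:
    """Log posterior score of a structure (up to the uniform-prior constant).

    Decomposable: the sum of family scores over all variables.
    """
    if cache is None:
        cache = FamilyCountCache(data, cfg)
    return sum(cache.family_score(v, g.parents(v)) for v in range(g.n_vars))


def _changed_families(g: DAGStructure, move: tuple[str, int, int]):
    """(child, old parents, new parents) for each family a move touches."""
    op, u, v = move
    pv = set(g.parents(v))
    if op == "add":
        if g.adj[u, v]:
            raise ValueError("invalid move: edge exists")
        return [(v, tuple(sorted(pv)), tuple(sorted(pv | {u})))]
    if op == "delete":
        if not g.adj[u, v]:
            raise ValueError("invalid move: edge absent")
        return [(v, tuple(sorted(pv)), tuple(sorted(pv - {u})))]
    if op == "reverse":
        if not g.adj[u, v]:
            raise ValueError("invalid move: edge absent")
        pu = set(g.parents(u))
        return [
            (v, tuple(sorted(pv)), tuple(sorted(pv - {u}))),
            (u, tuple(sorted(pu)), tuple(sorted(pu | {v}))),
        ]
    raise ValueError(f"unknown operator {op!r}")


def score_delta(g: DAGStructure, move: tuple[str, int, int], data=None,
                cfg: ScoreConfig | None = None,
                cache: FamilyCountCache | None = None) -> float:
    """Score change of a move, recomputing only the affected families.

    Equals ``dag_log_score(g') - dag_log_score(g)``: add/delete touch one
    family, reverse touches two.
    """
    if cache is None:
        cache = FamilyCountCache(data, cfg)
    delta = 0.0
    for child, old, new in _changed_families(g, move):
        delta += cache.family_score(child, new) - cache.family_score(child, old)
    return delta
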