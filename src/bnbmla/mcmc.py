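"""Metropolis-coupled MCMC over DAG structures.

The posterior ``P(G|D)`` over network structures is sampled by a random
walk whose states are DAGs and whose proposals are the three local
operators: add an edge (if acyclicity and the parent limit allow),
reverse an edge (likewise), and delete an edge.  The operator is chosen
uniformly; when a chosen operator has no valid instantiation on the
current graph it is resampled, which is equivalent to a uniform draw over
the operators that do have one.  The instantiation is uniform over the
operator's valid instantiations, and the Metropolis-Hastings correction
uses the exact neighborhood sizes of the current and proposed graphs, so
the asymmetric neighborhood structure of DAG space is accounted for
rather than assumed away.

Mixing over the multimodal structure posterior is helped by Metropolis
coupling (MC^3): ``n_chains`` chains target the tempered distributions
``P(D|G)^beta`` for a descending ladder of inverse temperatures starting
at 1.  Every ``swap_interval`` sweeps a uniformly chosen adjacent pair
proposes a state swap, accepted with the standard tempered ratio.  Only
cold-chain (beta = 1) states contribute to posterior estimates.

Validity bookkeeping per chain is incremental: a reflexive reachability
matrix answers cycle queries for additions in O(1) per candidate, and an
``adj @ closure`` product counts, exactly, the edges whose reversal would
leave an alternative directed path (and hence create a cycle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .scoring import DAGStructure, FamilyCountCache, ScoreConfig

__all__ = [
    "MCMCConfig",
    "StructureSampleStream",
    "propose_move",
    "mh_step",
    "mc3_run",
    "rhat_diagnostic",
    "RhatResult",
]


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler schedule.

    Defaults follow the published protocol (1e6 burn-in sweeps, 5e6
    post-burn-in sweeps, parent limit 8, feature evaluation every 10th
    sweep); chain count, temperature ladder and swap cadence are
    conventional MC^3 choices and fully configurable.
    """

    burn_in: int = 1_000_000
    n_steps: int = 5_000_000
    n_chains: int = 4
    inverse_temperatures: tuple[float, ...] | None = None
    swap_interval: int = 10
    seed: int = 0
    feature_eval_interval: int = 10
    max_parents: int = 8

    def ladder(self) -> np.ndarray:
        if self.inverse_temperatures is None:
            betas = np.linspace(1.0, 0.4, self.n_chains) if self.n_chains > 1 \
                else np.array([1.0])
        else:
            betas = np.asarray(self.inverse_temperatures, dtype=float)
            if len(betas) != self.n_chains:
                raise ValueError("ladder length must equal n_chains")
        if betas[0] != 1.0:
            raise ValueError("inverse_temperatures[0] must be 1.0")
        if len(betas) > 1 and not np.all(np.diff(betas) < 0):
            raise ValueError("inverse temperatures must be strictly decreasing")
        return betas


# -- incremental chain state ----------------------------------------------

def _reflexive_closure(adj: np.ndarray) -> np.ndarray:
    """Boolean reachability with True diagonal (every node reaches itself)."""
    n = adj.shape[0]
    r = (adj | np.eye(n, dtype=bool)).astype(np.uint8)
    while True:
        nxt = ((r @ r) > 0).astype(np.uint8)
        if np.array_equal(nxt, r):
            return r.astype(bool)
        r = nxt


class _ChainState:
    __slots__ = ("adj", "desc", "indeg", "fam", "total", "n_edges")

    def __init__(self, n_vars: int, cache: FamilyCountCache):
        self.adj = np.zeros((n_vars, n_vars), dtype=bool)
        self.desc = np.eye(n_vars, dtype=bool)
        self.indeg = np.zeros(n_vars, dtype=np.int64)
        self.fam = np.array(
            [cache.family_score(v, ()) for v in range(n_vars)], dtype=float
        )
        self.total = float(self.fam.sum())
        self.n_edges = 0

    @classmethod
    def from_dag(cls, g: DAGStructure, cache: FamilyCountCache) -> "_ChainState":
        st = cls(g.n_vars, cache)
        st.adj = g.adj.copy()
        st.desc = _reflexive_closure(st.adj)
        st.indeg = st.adj.sum(axis=0).astype(np.int64)
        st.fam = np.array(
            [cache.family_score(v, g.parents(v)) for v in range(g.n_vars)],
            dtype=float,
        )
        st.total = float(st.fam.sum())
        st.n_edges = g.n_edges
        return st


def _neighborhood(state: _ChainState, max_parents: int):
    """Valid-instantiation masks and counts for (add, delete, reverse)."""
    adj, desc, indeg = state.adj, state.desc, state.indeg
    add_mask = (~desc.T) & (~adj) & (indeg < max_parents)[None, :]
    n_add = int(np.count_nonzero(add_mask))
    n_del = state.n_edges
    adj_u8 = adj.astype(np.uint8)
    paths = adj_u8 @ desc.astype(np.uint8)  # u -> w => v counts, incl. w == v
    rev_mask = adj & ~(paths > adj_u8) & (indeg < max_parents)[:, None]
    n_rev = int(np.count_nonzero(rev_mask))
    return add_mask, rev_mask, n_add, n_del, n_rev


def _n_valid_ops(n_add: int, n_del: int, n_rev: int) -> int:
    return (n_add > 0) + (n_del > 0) + (n_rev > 0)


def _apply(state: _ChainState, move: tuple[str, int, int],
           cache: FamilyCountCache):
    """Mutate state in place; return an undo record."""
    op, u, v = move
    undo = {"move": move, "desc": state.desc,
            "fam": [], "total": state.total, "n_edges": state.n_edges}
    if op == "add":
        new_pv = tuple(sorted(set(np.flatnonzero(state.adj[:, v])) | {u}))
        state.adj[u, v] = True
        state.indeg[v] += 1
        state.n_edges += 1
        state.desc = state.desc | np.outer(state.desc[:, u], state.desc[v, :])
        undo["fam"].append((v, state.fam[v]))
        new_score = cache.family_score(v, new_pv)
        state.total += new_score - state.fam[v]
        state.fam[v] = new_score
    elif op == "delete":
        state.adj[u, v] = False
        state.indeg[v] -= 1
        state.n_edges -= 1
        state.desc = _reflexive_closure(state.adj)
        new_pv = tuple(np.flatnonzero(state.adj[:, v]))
        undo["fam"].append((v, state.fam[v]))
        new_score = cache.family_score(v, new_pv)
        state.total += new_score - state.fam[v]
        state.fam[v] = new_score
    elif op == "reverse":
        state.adj[u, v] = False
        state.adj[v, u] = True
        state.indeg[v] -= 1
        state.indeg[u] += 1
        state.desc = _reflexive_closure(state.adj)
        new_pv = tuple(np.flatnonzero(state.adj[:, v]))
        new_pu = tuple(np.flatnonzero(state.adj[:, u]))
        undo["fam"].append((v, state.fam[v]))
        undo["fam"].append((u, state.fam[u]))
        sv = cache.family_score(v, new_pv)
        su = cache.family_score(u, new_pu)
        state.total += (sv - state.fam[v]) + (su - state.fam[u])
        state.fam[v] = sv
        state.fam[u] = su
    else:
        raise ValueError(f"unknown operator {op!r}")
    return undo


def _revert(state: _ChainState, undo) -> None:
    op, u, v = undo["move"]
    if op == "add":
        state.adj[u, v] = False
        state.indeg[v] -= 1
    elif op == "delete":
        state.adj[u, v] = True
        state.indeg[v] += 1
    else:  # reverse
        state.adj[v, u] = False
        state.adj[u, v] = True
        state.indeg[u] -= 1
        state.indeg[v] += 1
    state.desc = undo["desc"]
    for child, score in undo["fam"]:
        state.fam[child] = score
    state.total = undo["total"]
    state.n_edges = undo["n_edges"]


_INVERSE_OP = {"add": "delete", "delete": "add", "reverse": "reverse"}


def _draw_move(state: _ChainState, max_parents: int, rng: np.random.Generator):
    """Pick (move, forward log-proposal-probability); None if no move exists."""
    add_mask, rev_mask, n_add, n_del, n_rev = _neighborhood(state, max_parents)
    ops = []
    if n_add:
        ops.append(("add", n_add))
    if n_del:
        ops.append(("delete", n_del))
    if n_rev:
        ops.append(("reverse", n_rev))
    if not ops:
        return None, 0.0
    op, count = ops[rng.integers(len(ops))]
    n = state.adj.shape[0]
    if op == "add":
        flat = np.flatnonzero(add_mask)
    elif op == "reverse":
        flat = np.flatnonzero(rev_mask)
    else:
        flat = np.flatnonzero(state.adj)
    e = int(flat[rng.integers(flat.size)])
    u, v = divmod(e, n)
    log_q = -math.log(len(ops)) - math.log(count)
    return (op, u, v), log_q


def _reverse_log_q(state: _ChainState, move, max_parents: int) -> float:
    """Log-probability of proposing the inverse move from the new state."""
    _, _, n_add, n_del, n_rev = _neighborhood(state, max_parents)
    counts = {"add": n_add, "delete": n_del, "reverse": n_rev}
    inv = _INVERSE_OP[move[0]]
    return -math.log(_n_valid_ops(n_add, n_del, n_rev)) - math.log(counts[inv])


def _mh_step_state(state: _ChainState, cache: FamilyCountCache, beta: float,
                   max_parents: int, rng: np.random.Generator) -> bool:
    move, log_q_fwd = _draw_move(state, max_parents, rng)
    if move is None:
        return False
    old_total = state.total
    undo = _apply(state, move, cache)
    log_q_rev = _reverse_log_q(state, move, max_parents)
    log_acc = beta * (state.total - old_total) + log_q_rev - log_q_fwd
    if log_acc >= 0 or rng.random() < math.exp(log_acc):
        return True
    _revert(state, undo)
    return False


# -- public single-step API ------------------------------------------------

def propose_move(
    g: DAGStructure,
    rng: np.random.Generator,
    max_parents: int = 8,
) -> tuple[tuple[str, int, int], float]:
    """Draw a proposal and its log-Hastings correction.

    Returns ``(move, log q(g'->g) - log q(g->g'))`` where the proposal
    probabilities come from exact neighborhood-size counting.
    """
    cache = _NullCache(g.n_vars)
    state = _ChainState.from_dag(g, cache)
    move, log_q_fwd = _draw_move(state, max_parents, rng)
    if move is None:
        raise ValueError("graph admits no valid move")
    _apply(state, move, cache)
    log_q_rev = _reverse_log_q(state, move, max_parents)
    return move, log_q_rev - log_q_fwd


class _NullCache:
    """Zero-score stand-in so structural helpers can run without data."""

    def __init__(self, n_vars: int):
        self.n_vars = n_vars

    def family_score(self, child, parents):
        return 0.0


def mh_step(
    g: DAGStructure,
    data,
    cfg: ScoreConfig | None = None,
    beta: float = 1.0,
    rng: np.random.Generator | None = None,
    cache: FamilyCountCache | None = None,
    max_parents: int | None = None,
) -> DAGStructure:
    """One Metropolis-Hastings step; returns the (possibly unchanged) state."""
    if rng is None:
        rng = np.random.default_rng()
    if cache is None:
        cache = FamilyCountCache(data, cfg)
    if max_parents is None:
        max_parents = cache.cfg.max_parents
    state = _ChainState.from_dag(g, cache)
    _mh_step_state(state, cache, beta, max_parents, rng)
    return DAGStructure(g.n_vars, state.adj)


# -- sample stream ---------------------------------------------------------

@dataclass
class StructureSampleStream:
    """Recorded cold-chain structures plus run statistics.

    Structures are deduplicated (the walk revisits few distinct DAGs
    relative to the step count); ``sample_ids`` maps each recorded sweep
    to its structure, so both the empirical distribution and per-step
    indicator series are recoverable.
    """

    n_vars: int
    var_names: list[str]
    packed: list[bytes]
    sample_ids: np.ndarray
    accept_rates: list[float]
    swap_attempts: int = 0
    swap_accepts: int = 0
    config: MCMCConfig | None = None
    score_config: ScoreConfig | None = None

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_unique(self) -> int:
        return len(self.packed)

    def adjacency(self, i: int) -> np.ndarray:
        bits = np.unpackbits(
            np.frombuffer(self.packed[i], dtype=np.uint8),
            count=self.n_vars * self.n_vars,
        )
        return bits.reshape(self.n_vars, self.n_vars).astype(bool)

    def weights(self) -> np.ndarray:
        w = np.bincount(self.sample_ids, minlength=len(self.packed))
        return w / self.n_samples

    def structures(self):
        """Yield (DAGStructure, weight) over unique recorded structures."""
        w = self.weights()
        for i in range(len(self.packed)):
            yield DAGStructure(self.n_vars, self.adjacency(i)), float(w[i])

    def indicator_values(self, fn: Callable[[DAGStructure], bool]) -> np.ndarray:
        """fn evaluated once per unique structure."""
        return np.array(
            [bool(fn(DAGStructure(self.n_vars, self.adjacency(i))))
             for i in range(len(self.packed))]
        )

    def indicator_series(self, fn: Callable[[DAGStructure], bool]) -> np.ndarray:
        """Per-recorded-sample 0/1 series for a structural feature."""
        per_unique = self.indicator_values(fn).astype(np.int8)
        return per_unique[self.sample_ids]

    def swap_rate(self) -> float:
        return self.swap_accepts / self.swap_attempts if self.swap_attempts else 0.0

    def manifest(self) -> dict:
        return {
            "n_vars": self.n_vars,
            "variables": self.var_names,
            "n_samples": int(self.n_samples),
            "n_unique_structures": self.n_unique,
            "accept_rates": [round(a, 4) for a in self.accept_rates],
            "swap_rate": round(self.swap_rate(), 4),
            "config": None if self.config is None else {
                "burn_in": self.config.burn_in,
                "n_steps": self.config.n_steps,
                "n_chains": self.config.n_chains,
                "inverse_temperatures": list(self.config.ladder()),
                "swap_interval": self.config.swap_interval,
                "feature_eval_interval": self.config.feature_eval_interval,
                "max_parents": self.config.max_parents,
                "seed": self.config.seed,
            },
        }


def mc3_run(
    data,
    score_cfg: ScoreConfig | None = None,
    mcmc_cfg: MCMCConfig | None = None,
    cache: FamilyCountCache | None = None,
) -> StructureSampleStream:
    """Run the coupled chains and record the cold chain.

    All chains start from the empty graph.  Fully reproducible from the
    seed: a single generator drives proposals and swaps in a fixed order.
    """
    from .data_model import DiscreteDataset

    mcmc_cfg = mcmc_cfg or MCMCConfig()
    if score_cfg is None:
        score_cfg = ScoreConfig(max_parents=mcmc_cfg.max_parents)
    if cache is None:
        cache = FamilyCountCache(data, score_cfg)
    n_vars = cache.n_vars
    var_names = (
        data.names if isinstance(data, DiscreteDataset)
        else [f"X{i}" for i in range(n_vars)]
    )
    betas = mcmc_cfg.ladder()
    rng = np.random.default_rng(mcmc_cfg.seed)
    states = [_ChainState(n_vars, cache) for _ in range(mcmc_cfg.n_chains)]
    max_parents = mcmc_cfg.max_parents

    accepts = np.zeros(mcmc_cfg.n_chains, dtype=np.int64)
    swap_attempts = 0
    swap_accepts = 0
    structure_ids: dict[bytes, int] = {}
    packed: list[bytes] = []
    sample_ids: list[int] = []

    total_sweeps = mcmc_cfg.burn_in + mcmc_cfg.n_steps
    interval = mcmc_cfg.feature_eval_interval
    for sweep in range(total_sweeps):
        for ci in range(mcmc_cfg.n_chains):
            if _mh_step_state(states[ci], cache, betas[ci], max_parents, rng):
                accepts[ci] += 1
        if mcmc_cfg.n_chains > 1 and (sweep + 1) % mcmc_cfg.swap_interval == 0:
            i = int(rng.integers(mcmc_cfg.n_chains - 1))
            swap_attempts += 1
            log_r = (betas[i] - betas[i + 1]) * (states[i + 1].total - states[i].total)
            if log_r >= 0 or rng.random() < math.exp(log_r):
                states[i], states[i + 1] = states[i + 1], states[i]
                swap_accepts += 1
        post = sweep - mcmc_cfg.burn_in
        if post >= 0 and post % interval == 0:
            key = np.packbits(states[0].adj).tobytes()
            sid = structure_ids.get(key)
            if sid is None:
                sid = len(packed)
                structure_ids[key] = sid
                packed.append(key)
            sample_ids.append(sid)

    return StructureSampleStream(
        n_vars=n_vars,
        var_names=list(var_names),
        packed=packed,
        sample_ids=np.asarray(sample_ids, dtype=np.int32),
        accept_rates=list(accepts / max(total_sweeps, 1)),
        swap_attempts=swap_attempts,
        swap_accepts=swap_accepts,
        config=mcmc_cfg,
        score_config=score_cfg,
    )


# -- convergence diagnostics ----------------------------------------------

@dataclass(frozen=True)
class RhatResult:
    per_feature: dict[str, float]
    max_rhat: float


def _gelman_rubin(series: np.ndarray) -> float:
    """Classic potential scale reduction for an (m, n) array of chains."""
    m, n = series.shape
    means = series.mean(axis=1)
    variances = series.var(axis=1, ddof=1)
    w = variances.mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else math.inf
    v = (n - 1) / n * w + b / n
    return math.sqrt(v / w)


def rhat_diagnostic(
    runs: Sequence[StructureSampleStream],
    features: dict[str, Callable[[DAGStructure], bool]],
) -> RhatResult:
    """Gelman-Rubin R-hat on each feature's indicator series across runs."""
    if len(runs) < 2:
        raise ValueError("R-hat needs at least 2 independent runs")
    n = min(r.n_samples for r in runs)
    if any(r.n_samples != n for r in runs):
        raise ValueError("runs must have equal post-burn-in length")
    per = {}
    for name, fn in features.items():
        series = np.stack([r.indicator_series(fn).astype(float) for r in runs])
        per[name] = _gelman_rubin(series)
    return RhatResult(per, max(per.values()) if per else math.nan)
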