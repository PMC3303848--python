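"""Posterior estimation from structure samples.

A structural feature's posterior is the average of its 0/1 indicator over
recorded cold-chain structures.  Markov blanket set (MBS) posteriors are
the empirical distribution of the target's blanket across samples, and
partial multivariate relevance (k-MBS) aggregates that table: the
posterior that a k-sized set is jointly strongly relevant is the summed
mass of every observed blanket containing it.  Aggregation necessarily
operates over the *visited* blanket table — a Monte Carlo run sees a
finite set of distinct structures — so k-MBS values are lower bounds
tight up to the unvisited mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .features import descendants_matrix
from .mcmc import StructureSampleStream
from .scoring import DAGStructure

__all__ = [
    "FeaturePosterior",
    "MBSTable",
    "KMBSTable",
    "estimate_feature_posterior",
    "mbs_posterior_table",
    "k_mbs_aggregate",
    "ap_approximation",
    "relevance_call",
    "peakness_curve",
    "relevance_report",
    "multitarget_report",
    "report_tables",
]

RELEVANCE_THRESHOLD = 0.5


@dataclass(frozen=True)
class FeaturePosterior:
    feature: str
    estimate: float
    n_samples: int
    mc_standard_error: float

    def __post_init__(self):
        if not 0.0 <= self.estimate <= 1.0:
            raise ValueError("posterior estimate must lie in [0, 1]")


@dataclass
class MBSTable:
    """Empirical posterior over Markov blanket sets of the target(s)."""

    targets: tuple[int, ...]
    probs: dict[frozenset, float]

    def sorted_items(self) -> list[tuple[frozenset, float]]:
        return sorted(self.probs.items(), key=lambda kv: (-kv[1], sorted(kv[0])))

    @property
    def total_mass(self) -> float:
        return float(sum(self.probs.values()))


@dataclass
class KMBSTable:
    k: int
    probs: dict[frozenset, float]

    def sorted_items(self) -> list[tuple[frozenset, float]]:
        return sorted(self.probs.items(), key=lambda kv: (-kv[1], sorted(kv[0])))


def estimate_feature_posterior(
    stream: StructureSampleStream, feature: Callable[[DAGStructure], bool],
    name: str = "feature",
) -> FeaturePosterior:
    """Mean indicator over recorded samples with binomial MC standard error."""
    if stream.n_samples == 0:
        raise ValueError("empty sample stream")
    per_unique = stream.indicator_values(feature).astype(float)
    p = float(np.clip(per_unique @ stream.weights(), 0.0, 1.0))
    se = float(np.sqrt(max(p * (1 - p), 0.0) / stream.n_samples))
    return FeaturePosterior(name, p, stream.n_samples, se)


def _blanket_mask(adj: np.ndarray, y: int) -> np.ndarray:
    adj_u8 = adj.astype(np.uint8)
    spouses = (adj_u8 @ adj_u8[y, :]) > 0  # share a child with y
    mask = adj[:, y] | adj[y, :] | spouses
    mask[y] = False
    return mask


def mbs_posterior_table(
    stream: StructureSampleStream, targets: int | Sequence[int]
) -> MBSTable:
    """Count each sample's blanket of the target (or target set)."""
    single = np.isscalar(targets)
    tgt = (int(targets),) if single else tuple(targets)
    if not tgt:
        raise ValueError("target set must be nonempty")
    if stream.n_samples == 0:
        raise ValueError("empty sample stream")
    w = stream.weights()
    probs: dict[frozenset, float] = {}
    for i in range(stream.n_unique):
        adj = stream.adjacency(i)
        mask = np.zeros(stream.n_vars, dtype=bool)
        for y in tgt:
            mask |= _blanket_mask(adj, y)
        for y in tgt:
            mask[y] = False
        s = frozenset(np.flatnonzero(mask).tolist())
        probs[s] = probs.get(s, 0.0) + float(w[i])
    return MBSTable(tgt, probs)


def k_mbs_aggregate(table: MBSTable, k: int) -> KMBSTable:
    """P(k-MBS = s) = sum of MBS mass over observed supersets of s.

    Monotone under inclusion: subsets always carry at least the mass of
    their supersets.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out: dict[frozenset, float] = {}
    for members, p in table.probs.items():
        if len(members) < k:
            continue
        for sub in combinations(sorted(members), k):
            key = frozenset(sub)
            out[key] = out.get(key, 0.0) + p
    return KMBSTable(k, out)


def ap_approximation(exist_posteriors: Iterable[float]) -> float:
    """Independence approximation of multi-target strong relevance.

    One minus the product of the per-target complements; exact when
    relevance events for different targets are independent.
    """
    prod = 1.0
    for p in exist_posteriors:
        if not 0.0 <= p <= 1.0:
            raise ValueError("posteriors must lie in [0, 1]")
        prod *= 1.0 - p
    return 1.0 - prod


def relevance_call(p: float, threshold: float = RELEVANCE_THRESHOLD) -> bool:
    """A variable is called relevant when its posterior reaches the
    threshold (inclusive; 0.5 by convention)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("posterior must lie in [0, 1]")
    return p >= threshold


def peakness_curve(table: MBSTable | KMBSTable, top_n: int = 100) -> np.ndarray:
    """Descending (rank, probability) series of the most probable sets.

    A peaked curve (mass concentrated at low ranks) indicates the data
    suffice for a multivariate read-out; a flat one does not.
    """
    if not table.probs:
        raise ValueError("empty table")
    probs = [p for _, p in table.sorted_items()[:top_n]]
    return np.array(list(enumerate(probs, start=1)), dtype=float)


def plot_peakness(curves: dict[str, np.ndarray], path=None):
    """Optional matplotlib rendering of peakness curves."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    for label, curve in curves.items():
        ax.plot(curve[:, 0], curve[:, 1], marker=".", label=label)
    ax.set_xlabel("rank of set")
    ax.set_ylabel("posterior probability")
    ax.legend()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


# -- report tables ---------------------------------------------------------

def _pair_vectors(adj: np.ndarray, desc: np.ndarray, y: int) -> dict[str, np.ndarray]:
    adj_u8 = adj.astype(np.uint8)
    dcr = adj[:, y] | adj[y, :]
    tcr = desc[:, y] | desc[y, :]
    confr = (desc.T.astype(np.uint8) @ desc[:, y].astype(np.uint8)) > 0
    common_child = (adj_u8 @ adj_u8[y, :]) > 0
    pir = common_child & ~dcr
    vec = {
        "dcr": dcr,
        "tcr": tcr,
        "confr": confr,
        "assoc": dcr | tcr | confr,
        "pir": pir,
        "sr": dcr | pir,
        "mediated_only": tcr & ~dcr,
    }
    for v in vec.values():
        v[y] = False
    return vec


def relevance_report(
    stream: StructureSampleStream,
    target: int | str,
    predictors: Sequence[int | str] | None = None,
) -> pd.DataFrame:
    """Per-predictor dependency-type posteriors against one target.

    Columns mirror the standard single-target layout: associated, direct
    (D-Relevant), strong (S-Relevant), interaction (pure interactionist)
    and transitive; ``mediated_only`` excludes the direct edge from the
    transitive count.
    """
    y = stream.var_names.index(target) if isinstance(target, str) else int(target)
    n = stream.n_vars
    if predictors is None:
        pred_idx = [i for i in range(n) if i != y]
    else:
        pred_idx = [
            stream.var_names.index(p) if isinstance(p, str) else int(p)
            for p in predictors
        ]
        missing = [p for p in pred_idx if not 0 <= p < n]
        if missing:
            raise KeyError(f"predictor index out of range: {missing}")
    w = stream.weights()
    acc = {f: np.zeros(n) for f in
           ("assoc", "dcr", "sr", "pir", "tcr", "mediated_only", "confr")}
    for i in range(stream.n_unique):
        adj = stream.adjacency(i)
        desc = descendants_matrix(adj)
        vec = _pair_vectors(adj, desc, y)
        for f in acc:
            acc[f] += w[i] * vec[f]
    frame = pd.DataFrame(
        {
            "associated": acc["assoc"][pred_idx],
            "direct": acc["dcr"][pred_idx],
            "strong": acc["sr"][pred_idx],
            "interaction": acc["pir"][pred_idx],
            "transitive": acc["tcr"][pred_idx],
            "mediated_only": acc["mediated_only"][pred_idx],
            "confounded": acc["confr"][pred_idx],
        },
        index=[stream.var_names[i] for i in pred_idx],
    )
    frame.index.name = "variable"
    return frame


def multitarget_report(
    stream: StructureSampleStream,
    targets: Sequence[int | str],
    predictors: Sequence[int | str] | None = None,
) -> pd.DataFrame:
    """Exist/Only/OtherThan/AP/MT decomposition over a target set."""
    tgt = [
        stream.var_names.index(t) if isinstance(t, str) else int(t) for t in targets
    ]
    n = stream.n_vars
    if predictors is None:
        pred_idx = [i for i in range(n) if i not in tgt]
    else:
        pred_idx = [
            stream.var_names.index(p) if isinstance(p, str) else int(p)
            for p in predictors
        ]
    w = stream.weights()
    m = len(tgt)
    exist = np.zeros((n, m))
    mt = np.zeros(n)
    edge_any = np.zeros(n)
    only = np.zeros((n, m))
    other = np.zeros((n, m))
    for i in range(stream.n_unique):
        adj = stream.adjacency(i)
        desc = descendants_matrix(adj)
        sr = np.stack([_pair_vectors(adj, desc, y)["sr"] for y in tgt], axis=1)
        any_sr = sr.any(axis=1)
        exist += w[i] * sr
        mt += w[i] * any_sr
        e = np.zeros(n, dtype=bool)
        for y in tgt:
            e |= adj[:, y] | adj[y, :]
        for y in tgt:
            e[y] = False
        edge_any += w[i] * e
        n_sr = sr.sum(axis=1)
        only += w[i] * (sr & (n_sr == 1)[:, None])
        other += w[i] * ((n_sr[:, None] - sr) > 0)
    # guard against float accumulation drifting a hair past [0, 1]
    for arr in (exist, mt, edge_any, only, other):
        np.clip(arr, 0.0, 1.0, out=arr)
    tgt_names = [stream.var_names[y] for y in tgt]
    data = {}
    for j, name in enumerate(tgt_names):
        data[f"exist_{name}"] = exist[pred_idx, j]
    data["ap"] = [ap_approximation(exist[i, :]) for i in pred_idx]
    for j, name in enumerate(tgt_names):
        data[f"only_{name}"] = only[pred_idx, j]
    for j, name in enumerate(tgt_names):
        data[f"other_than_{name}"] = other[pred_idx, j]
    data["mt"] = mt[pred_idx]
    data["edge_to_any"] = edge_any[pred_idx]
    frame = pd.DataFrame(data, index=[stream.var_names[i] for i in pred_idx])
    frame.index.name = "variable"
    return frame


def report_tables(
    stream: StructureSampleStream,
    targets: Sequence[int | str],
    predictors: Sequence[int | str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Standard posterior reports for one run: a dependency-type table per
    target, plus the multi-target decomposition when several targets are
    analyzed jointly."""
    tgt_names = [
        t if isinstance(t, str) else stream.var_names[int(t)] for t in targets
    ]
    unknown = [t for t in tgt_names if t not in stream.var_names]
    if unknown:
        raise KeyError(f"target(s) not in stream: {unknown}")
    out = {
        f"relevance_{name}": relevance_report(stream, name, predictors)
        for name in tgt_names
    }
    if len(tgt_names) > 1:
        out["multi_target"] = multitarget_report(stream, tgt_names, predictors)
    return out
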