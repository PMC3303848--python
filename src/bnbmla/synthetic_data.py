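"""Synthetic genotype-phenotype datasets with known relevance structure.

The generator emulates a candidate-region case-control design: biallelic
SNPs drawn under Hardy-Weinberg equilibrium, linkage-disequilibrium proxy
SNPs produced by a per-allele copy process, direct logistic genotype
effects on binary phenotypes, purely epistatic SNP pairs with no marginal
effect, and a small directed wiring among phenotypes (e.g. an allergy
chain: IgE level feeding eosinophil count, rhinitis and asthma).  Every
simulated pair (SNP, target) carries a ground-truth label — direct,
pure-interaction, transitive-only or null — so recovery of the planted
structure is testable.

LD is modeled as allele copying with a fidelity parameter rather than
haplotype blocks: the proxy's allele equals the source allele with
probability ``fidelity`` and is otherwise redrawn from the population
frequency.  This is analytically tractable (the allelic correlation is
``fidelity``, so r^2 = fidelity^2) and produces exactly the
transitive-but-not-direct structure the analysis must distinguish.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .data_model import DiscreteDataset, VariableMeta, discretize_continuous
from .scoring import DAGStructure

__all__ = [
    "SNPSpec",
    "LDProxySpec",
    "GenotypeEffect",
    "EpistasisSpec",
    "PhenotypeSpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_dataset",
    "illustration_dag",
    "recovery_scenario",
    "two_target_scenario",
    "clinical_scenario",
]


@dataclass(frozen=True)
class SNPSpec:
    name: str
    maf: float

    def __post_init__(self):
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf}")


@dataclass(frozen=True)
class LDProxySpec:
    """A SNP whose alleles copy another SNP's alleles with given fidelity."""

    name: str
    source: str
    fidelity: float

    def __post_init__(self):
        if not 0.0 <= self.fidelity <= 1.0:
            raise ValueError("fidelity must be in [0, 1]")


@dataclass(frozen=True)
class GenotypeEffect:
    """Additive per-minor-allele log-odds (binary target) or shift of the
    log-scale mean (continuous target)."""

    target: str
    snp: str
    log_or: float


@dataclass(frozen=True)
class EpistasisSpec:
    """A SNP pair acting only through an interaction pattern.

    ``xor``: the risk term is the exclusive-or of the two heterozygosity
    indicators — at MAF 0.5 each indicator is Bernoulli(1/2), so both
    marginal effects vanish exactly.  ``product``: the centered genotype
    product (g_a - 1)(g_b - 1), likewise marginal-free at MAF 0.5.
    """

    target: str
    snp_a: str
    snp_b: str
    log_or: float
    pattern: str = "xor"

    def __post_init__(self):
        if self.pattern not in ("xor", "product"):
            raise ValueError(f"unknown epistasis pattern {self.pattern!r}")


@dataclass(frozen=True)
class PhenotypeSpec:
    """One phenotype node.

    ``parent_coefs`` wires phenotype-on-phenotype edges (binary parents
    enter as 0/1 indicators, continuous parents as standardized log
    values).  Binary phenotypes follow a logistic model; continuous ones
    a log-normal whose log-mean shifts with genotype and parent effects.
    """

    name: str
    kind: str = "binary"
    intercept: float = 0.0
    parent_coefs: dict[str, float] = field(default_factory=dict)
    sigma: float = 1.0
    discretize: str = "median"
    is_target: bool = True

    def __post_init__(self):
        if self.kind not in ("binary", "continuous"):
            raise ValueError(f"unknown phenotype kind {self.kind!r}")


@dataclass(frozen=True)
class SimulationConfig:
    n_individuals: int
    snps: tuple[SNPSpec, ...]
    ld: tuple[LDProxySpec, ...] = ()
    effects: tuple[GenotypeEffect, ...] = ()
    epistasis: tuple[EpistasisSpec, ...] = ()
    phenotypes: tuple[PhenotypeSpec, ...] = ()
    seed: int = 0

    def phenotype_order(self) -> list[str]:
        g = nx.DiGraph()
        g.add_nodes_from(p.name for p in self.phenotypes)
        for p in self.phenotypes:
            for parent in p.parent_coefs:
                g.add_edge(parent, p.name)
        try:
            return list(nx.topological_sort(g))
        except nx.NetworkXUnfeasible as exc:
            raise ValueError("phenotype wiring contains a cycle") from exc


@dataclass
class GroundTruth:
    """Answer key: one mutually exclusive label per (SNP, target) pair."""

    labels: dict[tuple[str, str], str]

    def label(self, snp: str, target: str) -> str:
        return self.labels.get((snp, target), "null")

    def pairs_with(self, label: str) -> list[tuple[str, str]]:
        return sorted(k for k, v in self.labels.items() if v == label)

    def to_dict(self) -> dict:
        return {f"{s}|{t}": v for (s, t), v in sorted(self.labels.items())}


def simulate_genotypes(
    cfg: SimulationConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Draw founder SNPs under HWE and derive LD proxies by allele copying."""
    n = cfg.n_individuals
    alleles: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    mafs = {s.name: s.maf for s in cfg.snps}
    for s in cfg.snps:
        a1 = (rng.random(n) < s.maf).astype(np.int8)
        a2 = (rng.random(n) < s.maf).astype(np.int8)
        alleles[s.name] = (a1, a2)
    for proxy in cfg.ld:
        if proxy.source not in alleles:
            raise KeyError(f"LD source {proxy.source!r} not among founder SNPs")
        src1, src2 = alleles[proxy.source]
        maf = mafs[proxy.source]
        out = []
        for src in (src1, src2):
            copy = rng.random(n) < proxy.fidelity
            fresh = (rng.random(n) < maf).astype(np.int8)
            out.append(np.where(copy, src, fresh).astype(np.int8))
        alleles[proxy.name] = (out[0], out[1])
        mafs[proxy.name] = maf
    return {name: (a1 + a2).astype(np.int8) for name, (a1, a2) in alleles.items()}


def _epistasis_term(spec: EpistasisSpec, ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    if spec.pattern == "xor":
        return spec.log_or * ((ga % 2) ^ (gb % 2)).astype(float)
    return spec.log_or * (ga - 1.0) * (gb - 1.0)


def simulate_phenotypes(
    genotypes: dict[str, np.ndarray],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Draw phenotypes in topological order; return values and answer key.

    Binary phenotypes are Bernoulli with a logistic link over numeric
    genotypes, interaction terms, and parent phenotype contributions;
    continuous phenotypes are log-normal with the same linear predictor
    shifting the log-mean.
    """
    order = cfg.phenotype_order()
    specs = {p.name: p for p in cfg.phenotypes}
    n = cfg.n_individuals
    values: dict[str, np.ndarray] = {}
    covariate: dict[str, np.ndarray] = {}
    for name in order:
        spec = specs[name]
        eta = np.full(n, spec.intercept, dtype=float)
        for eff in cfg.effects:
            if eff.target == name:
                eta += eff.log_or * genotypes[eff.snp].astype(float)
        for epi in cfg.epistasis:
            if epi.target == name:
                eta += _epistasis_term(epi, genotypes[epi.snp_a], genotypes[epi.snp_b])
        for parent, coef in spec.parent_coefs.items():
            eta += coef * covariate[parent]
        if spec.kind == "binary":
            p = 1.0 / (1.0 + np.exp(-eta))
            val = (rng.random(n) < p).astype(np.int8)
            values[name] = val
            covariate[name] = val.astype(float)
        else:
            log_val = eta + spec.sigma * rng.standard_normal(n)
            values[name] = np.exp(log_val)
            sd = log_val.std()
            covariate[name] = (log_val - log_val.mean()) / (sd if sd > 0 else 1.0)
    return values, _ground_truth(cfg)


def _ground_truth(cfg: SimulationConfig) -> GroundTruth:
    pheno_graph = nx.DiGraph()
    pheno_graph.add_nodes_from(p.name for p in cfg.phenotypes)
    for p in cfg.phenotypes:
        for parent in p.parent_coefs:
            pheno_graph.add_edge(parent, p.name)
    targets = [p.name for p in cfg.phenotypes if p.is_target]
    snp_names = [s.name for s in cfg.snps] + [p.name for p in cfg.ld]
    proxy_source = {p.name: p.source for p in cfg.ld}

    direct: dict[str, set[str]] = {t: set() for t in targets}
    interacting: dict[str, set[str]] = {t: set() for t in targets}
    affected: dict[str, set[str]] = {p.name: set() for p in cfg.phenotypes}
    for eff in cfg.effects:
        affected[eff.target].add(eff.snp)
        if eff.target in direct:
            direct[eff.target].add(eff.snp)
    for epi in cfg.epistasis:
        affected[epi.target].update((epi.snp_a, epi.snp_b))
        if epi.target in interacting:
            interacting[epi.target].update((epi.snp_a, epi.snp_b))

    labels: dict[tuple[str, str], str] = {}
    for t in targets:
        upstream: set[str] = set()
        for p in pheno_graph.nodes:
            if p != t and nx.has_path(pheno_graph, p, t):
                upstream |= affected[p]
        for snp in snp_names:
            src = proxy_source.get(snp)
            if snp in direct[t]:
                label = "direct"
            elif snp in interacting[t]:
                label = "pure_interaction"
            elif snp in upstream:
                label = "transitive_only"
            elif src is not None and (
                src in direct[t] or src in interacting[t] or src in upstream
            ):
                label = "transitive_only"
            else:
                label = "null"
            labels[(snp, t)] = label
    return GroundTruth(labels)


def simulate_dataset(
    cfg: SimulationConfig, seed: int | None = None
) -> tuple[DiscreteDataset, GroundTruth]:
    """Full pipeline: genotypes, phenotypes, discretization, dataset assembly.

    Deterministic for a given config and seed (identical bytes).
    Continuous phenotypes are discretized with the scheme named in their
    spec before entering the dataset.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    genotypes = simulate_genotypes(cfg, rng)
    phenotypes, truth = simulate_phenotypes(genotypes, cfg, rng)
    variables, cols = [], []
    for name, g in genotypes.items():
        levels = tuple(int(v) for v in np.unique(g))
        dense = np.searchsorted(np.array(levels), g).astype(np.int16)
        variables.append(
            VariableMeta(name, len(levels), role="predictor", kind="genotype",
                         levels=levels)
        )
        cols.append(dense)
    for spec in cfg.phenotypes:
        vals = phenotypes[spec.name]
        if spec.kind == "continuous":
            codes, _ = discretize_continuous(vals, scheme=spec.discretize)
        else:
            codes = vals.astype(np.int16)
        levels = tuple(int(v) for v in np.unique(codes))
        dense = np.searchsorted(np.array(levels), codes).astype(np.int16)
        variables.append(
            VariableMeta(
                spec.name, len(levels),
                role="target" if spec.is_target else "predictor",
                kind="phenotype", levels=levels,
            )
        )
        cols.append(dense)
    return DiscreteDataset(variables, np.column_stack(cols)), truth


# -- fixture DAG for the feature semantics --------------------------------

ILLUSTRATION_NAMES = (
    "Y1", "Y2", "Y3",
    "SNP1", "SNP2", "SNP3", "SNP4", "SNP5", "SNP6", "SNP7", "SNP8", "SNP9",
)

_ILLUSTRATION_EDGES = (
    ("SNP1", "Y1"),
    ("SNP1", "SNP3"),
    ("Y1", "Y2"),
    ("SNP7", "Y2"),
    ("Y2", "Y3"),
    ("SNP9", "Y3"),
    ("Y3", "SNP4"),
    ("SNP4", "SNP5"),
    ("SNP4", "SNP6"),
    ("SNP6", "SNP5"),
)


def illustration_dag() -> tuple[DAGStructure, list[str]]:
    """A fixed DAG over three phenotypes and nine SNPs exhibiting every
    dependency type at once.

    Constructed so that: SNP1 is directly relevant to Y1; there are two
    directed paths between Y3 and SNP5 (transitive); SNP1 is a common
    ancestor of Y2 and SNP3 (confounded); Y1 and SNP7 share a child
    (pure interaction); MBS(Y2) = {Y1, SNP9, Y3, SNP7}; and
    MBS({Y1, Y2, Y3}) = {SNP1, SNP4, SNP7, SNP9}.
    """
    names = list(ILLUSTRATION_NAMES)
    idx = {n: i for i, n in enumerate(names)}
    g = DAGStructure.from_edges(
        len(names), [(idx[u], idx[v]) for u, v in _ILLUSTRATION_EDGES]
    )
    return g, names


# -- scenario bundles ------------------------------------------------------

_DEFAULT_MAFS = (0.30, 0.15, 0.50, 0.50, 0.25, 0.40, 0.10, 0.35, 0.20, 0.45,
                 0.12, 0.28, 0.33, 0.18, 0.42, 0.22, 0.38, 0.08, 0.26, 0.48)


def recovery_scenario(n_individuals: int = 1500, seed: int = 0) -> SimulationConfig:
    """One binary target, 20 SNPs, with a planted direct effect (snp01),
    an LD proxy of it (snp02, fidelity 0.9, no own effect), a purely
    epistatic XOR pair at MAF 0.5 (snp03, snp04), and null SNPs.

    Effect sizes are moderate-to-strong for a candidate-gene study
    (per-allele log-OR 0.6; interaction log-OR 1.0) so that the planted
    structure is recoverable at this sample size.
    """
    snps = [SNPSpec(f"snp{i + 1:02d}", _DEFAULT_MAFS[i]) for i in range(19)]
    ld = (LDProxySpec("snp02", "snp01", fidelity=0.9),)
    # snp02 is generated as a proxy, not a founder
    snps = [s for s in snps if s.name != "snp02"]
    snps.append(SNPSpec("snp20", _DEFAULT_MAFS[19]))
    return SimulationConfig(
        n_individuals=n_individuals,
        snps=tuple(snps),
        ld=ld,
        effects=(GenotypeEffect("asthma", "snp01", 0.6),),
        epistasis=(EpistasisSpec("asthma", "snp03", "snp04", 1.0, "xor"),),
        phenotypes=(PhenotypeSpec("asthma", "binary", intercept=-0.6),),
        seed=seed,
    )


def two_target_scenario(n_individuals: int = 1500, seed: int = 0) -> SimulationConfig:
    """Two wired binary targets: snp01 affects rhinitis only, rhinitis
    feeds asthma, and snp02 affects asthma directly.  The snp01-asthma
    dependence is therefore purely phenotype-mediated (transitive)."""
    snps = tuple(
        SNPSpec(f"snp{i + 1:02d}", _DEFAULT_MAFS[i]) for i in range(10)
    )
    return SimulationConfig(
        n_individuals=n_individuals,
        snps=snps,
        effects=(
            GenotypeEffect("rhinitis", "snp01", 0.7),
            GenotypeEffect("asthma", "snp02", 0.6),
        ),
        phenotypes=(
            PhenotypeSpec("rhinitis", "binary", intercept=-0.8),
            PhenotypeSpec("asthma", "binary", intercept=-1.0,
                          parent_coefs={"rhinitis": 1.2}),
        ),
        seed=seed,
    )


def clinical_scenario(n_individuals: int = 200, seed: int = 0) -> SimulationConfig:
    """Small clinical design: four targets (a continuous IgE-like level,
    a continuous eosinophil-like count, rhinitis, asthma) wired as an
    allergy chain, with one SNP influencing the IgE-like level and one
    influencing asthma directly."""
    snps = tuple(SNPSpec(f"snp{i + 1:02d}", _DEFAULT_MAFS[i]) for i in range(8))
    return SimulationConfig(
        n_individuals=n_individuals,
        snps=snps,
        effects=(
            GenotypeEffect("ige", "snp01", 0.5),
            GenotypeEffect("asthma", "snp02", 0.7),
        ),
        phenotypes=(
            PhenotypeSpec("ige", "continuous", intercept=4.5, sigma=0.8),
            PhenotypeSpec("eos", "continuous", intercept=-1.5, sigma=0.6,
                          parent_coefs={"ige": 0.5}),
            PhenotypeSpec("rhinitis", "binary", intercept=-0.8,
                          parent_coefs={"ige": 0.7}),
            PhenotypeSpec("asthma", "binary", intercept=-0.7,
                          parent_coefs={"eos": 0.6, "rhinitis": 0.8}),
        ),
        seed=seed,
    )
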