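"""Quality control and frequentist association baselines.

SNP-level QC mirrors standard case-control practice: monomorphic markers
are dropped, markers out of Hardy-Weinberg equilibrium *in controls*
(chi-square goodness of fit, p < 0.005) are dropped, and markers whose
genotyping call rate is at or below 90% are dropped.  Association is
tested with allele-count and genotype-class chi-square statistics (no
continuity correction), cross-product odds ratios with Woolf (log-OR)
confidence intervals, Bonferroni control across markers, haplotype odds
ratios reconstructed from haplotype frequencies, and logistic-regression
interaction fits with numeric 0/1/2 genotype coding.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import MISSING, DiscreteDataset

__all__ = [
    "ContingencyTable2x2",
    "QCReport",
    "hwe_test",
    "allele_association_test",
    "genotype_association_test",
    "qc_filter",
    "bonferroni_threshold",
    "display_significance",
    "haplotype_or_from_frequencies",
    "logistic_interaction_fit",
    "association_table",
]

Z95 = stats.norm.ppf(0.975)


class ContingencyTable2x2(NamedTuple):
    """Counts (case-exposed, case-unexposed, control-exposed, control-unexposed)."""

    a: float
    b: float
    c: float
    d: float


class HWEResult(NamedTuple):
    chi2: float
    p: float


class AlleleTestResult(NamedTuple):
    chi2: float
    p: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool = False


@dataclass
class GenotypeTestResult:
    chi2: float
    p: float
    df: int
    collapsed: bool
    recessive: AlleleTestResult | None
    dominant: AlleleTestResult | None


@dataclass
class QCReport:
    """Partition of the input SNPs by QC outcome."""

    removed_monomorphic: list[str] = field(default_factory=list)
    removed_hwe: list[str] = field(default_factory=list)
    removed_callrate: list[str] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "removed_monomorphic": self.removed_monomorphic,
            "removed_hwe": self.removed_hwe,
            "removed_callrate": self.removed_callrate,
            "retained": self.retained,
        }


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> HWEResult:
    """Chi-square goodness of fit against Hardy-Weinberg proportions.

    Expected genotype counts come from the estimated allele frequency
    (p^2, 2pq, q^2); 1 degree of freedom.  Symmetric under allele
    relabeling.  Raises on monomorphic input, where expected heterozygote
    counts vanish.
    """
    n = n_AA + n_Aa + n_aa
    if n <= 0:
        raise ValueError("empty genotype counts")
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        raise ValueError("monomorphic marker: Hardy-Weinberg test undefined")
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return HWEResult(chi2, float(stats.chi2.sf(chi2, df=1)))


def _woolf_ci(a: float, b: float, c: float, d: float) -> tuple[float, float, float]:
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    return or_, math.exp(log_or - Z95 * se), math.exp(log_or + Z95 * se)


def _chi2_2x2(a, b, c, d) -> tuple[float, float]:
    table = np.array([[a, b], [c, d]], dtype=float)
    n = table.sum()
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero margin in 2x2 table")
    expected = row * col / n
    chi2 = float(((table - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def allele_association_test(t: ContingencyTable2x2) -> AlleleTestResult:
    """Allele-count chi-square with cross-product OR and 95% Woolf CI.

    A zero cell triggers the Haldane 0.5 correction (applied to every
    cell for the OR/CI) and is flagged in the result.
    """
    a, b, c, d = t
    if min(a, b, c, d) < 0:
        raise ValueError("negative count")
    chi2, p = _chi2_2x2(a, b, c, d)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_, lo, hi = _woolf_ci(a, b, c, d)
    return AlleleTestResult(chi2, p, or_, lo, hi, corrected)


def genotype_association_test(
    case_counts: Sequence[int], control_counts: Sequence[int]
) -> GenotypeTestResult:
    """Overall genotype-distribution chi-square plus model-specific tests.

    The 2x3 table gives a 2-df statistic; the recessive test collapses to
    minor-homozygote vs the rest, the dominant test to carrier vs
    non-carrier.  An empty genotype class collapses the overall test to
    1 df with a flag.
    """
    case = np.asarray(case_counts, dtype=float)
    control = np.asarray(control_counts, dtype=float)
    if case.shape != (3,) or control.shape != (3,):
        raise ValueError("expected 3 genotype classes per group")
    if case.sum() == 0 or control.sum() == 0:
        raise ValueError("empty group")
    table = np.vstack([case, control])
    nonempty = table.sum(axis=0) > 0
    collapsed = int(nonempty.sum()) < 3
    if collapsed:
        warnings.warn("empty genotype class: collapsing to 1-df test")
    sub = table[:, nonempty]
    if sub.shape[1] < 2:
        raise ValueError("fewer than two observed genotype classes")
    chi2, p, df, _ = stats.chi2_contingency(sub, correction=False)

    def _2x2(case_exp, case_un, ctl_exp, ctl_un):
        if min(case_exp + case_un, ctl_exp + ctl_un) == 0:
            return None
        vals = (case_exp, case_un, ctl_exp, ctl_un)
        if 0 in ((case_exp + ctl_exp), (case_un + ctl_un)):
            return None
        c2, pv = _chi2_2x2(*vals)
        zero = min(vals) == 0
        v = tuple(x + 0.5 for x in vals) if zero else vals
        or_, lo, hi = _woolf_ci(*v)
        return AlleleTestResult(c2, pv, or_, lo, hi, zero)

    recessive = _2x2(case[2], case[0] + case[1], control[2], control[0] + control[1])
    dominant = _2x2(case[1] + case[2], case[0], control[1] + control[2], control[0])
    return GenotypeTestResult(float(chi2), float(p), int(df), collapsed,
                              recessive, dominant)


def qc_filter(
    dataset: DiscreteDataset,
    controls_mask: np.ndarray,
    hwe_p_max: float = 0.005,
    callrate_min: float = 0.90,
) -> tuple[DiscreteDataset, QCReport]:
    """Remove monomorphic, Hardy-Weinberg-deviating and low-call-rate SNPs.

    The Hardy-Weinberg screen uses control individuals only; call rates
    are computed on the dataset as given, i.e. before any complete-case
    filtering.  Non-genotype variables pass through untouched.
    """
    controls_mask = np.asarray(controls_mask, dtype=bool)
    if controls_mask.shape != (dataset.n_rows,):
        raise ValueError("controls_mask length mismatch")
    if not controls_mask.any():
        raise ValueError("controls_mask selects no rows")
    report = QCReport()
    keep: list[str] = []
    rates = dataset.call_rates()
    for v in dataset.variables:
        if v.kind != "genotype" or v.role == "target":
            keep.append(v.name)
            continue
        col = dataset.column(v.name)
        observed = col[col != MISSING]
        if np.unique(observed).size <= 1:
            report.removed_monomorphic.append(v.name)
            continue
        if rates[v.name] <= callrate_min:
            report.removed_callrate.append(v.name)
            continue
        ctl = col[controls_mask]
        ctl = ctl[ctl != MISSING]
        counts = [0, 0, 0]
        for code, label in enumerate(v.levels):
            counts[int(label)] = int((ctl == code).sum())
        try:
            hwe = hwe_test(*counts)
            if hwe.p < hwe_p_max:
                report.removed_hwe.append(v.name)
                continue
        except ValueError:
            # monomorphic among controls only: HWE screen inapplicable
            pass
        keep.append(v.name)
        report.retained.append(v.name)
    filtered = dataset.subset_columns(keep)
    return filtered, report


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise corrected per-test significance level alpha/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def display_significance(threshold: float) -> float:
    """Round to one significant figure for display (0.00049 -> 0.0005)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    exponent = math.floor(math.log10(threshold))
    return round(threshold, -exponent)


class HaplotypeORResult(NamedTuple):
    odds_ratio: float
    ci_low: float
    ci_high: float
    table: ContingencyTable2x2


def haplotype_or_from_frequencies(
    f_case: float,
    f_control: float,
    n_case_chrom: int,
    n_control_chrom: int,
) -> HaplotypeORResult:
    """Odds ratio of carrying a haplotype, from frequencies and chromosome counts.

    The 2x2 chromosome-count table is reconstructed by rounding
    ``frequency x chromosomes`` to the nearest count; the OR is the
    cross-product with a Woolf CI.  This count-based OR can differ in the
    last digit from a conditional-logistic haplotype OR fitted on
    phase-probability-weighted data.
    """
    for f in (f_case, f_control):
        if not 0.0 < f < 1.0:
            raise ValueError("haplotype frequency must be in (0, 1)")
    a = round(f_case * n_case_chrom)
    b = n_case_chrom - a
    c = round(f_control * n_control_chrom)
    d = n_control_chrom - c
    or_, lo, hi = _woolf_ci(a, b, c, d)
    return HaplotypeORResult(or_, lo, hi, ContingencyTable2x2(a, b, c, d))


class TermFit(NamedTuple):
    term: str
    coef: float
    exp_coef: float
    ci_low: float
    ci_high: float
    p: float


def logistic_interaction_fit(
    y: Sequence[int], terms: dict[str, Sequence[float]] | pd.DataFrame
) -> list[TermFit]:
    """Maximum-likelihood logistic fit with all terms entered.

    ``terms`` holds the predictors, including any product (interaction)
    columns, with genotypes coded numerically 0/1/2.  Returns Wald CIs
    and p-values per term.  Raises on separation or non-convergence,
    naming the model terms.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    frame = pd.DataFrame(terms)
    names = list(frame.columns)
    x = sm.add_constant(frame.to_numpy(dtype=float), has_constant="add")
    yv = np.asarray(y, dtype=float)
    if yv.shape[0] <= x.shape[1]:
        raise ValueError("more terms than observations")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            model = sm.Logit(yv, x)
            res = model.fit(disp=0, maxiter=100)
    except (PerfectSeparationError, np.linalg.LinAlgError, RuntimeWarning) as exc:
        raise RuntimeError(
            f"logistic fit failed (separation or non-convergence) for terms "
            f"{names}: {exc}"
        ) from exc
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError(f"logistic fit did not converge for terms {names}")
    out = []
    ci = res.conf_int()
    for i, name in enumerate(names, start=1):
        out.append(
            TermFit(
                name,
                float(res.params[i]),
                float(np.exp(res.params[i])),
                float(np.exp(ci[i, 0])),
                float(np.exp(ci[i, 1])),
                float(res.pvalues[i]),
            )
        )
    return out


def association_table(
    dataset: DiscreteDataset,
    case_mask: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-SNP allele and genotype association report with Bonferroni flags."""
    case_mask = np.asarray(case_mask, dtype=bool)
    snps = [
        v for v in dataset.variables if v.kind == "genotype" and v.role != "target"
    ]
    rows = []
    threshold = bonferroni_threshold(alpha, max(len(snps), 1))
    for v in snps:
        col = dataset.column(v.name)
        ok = col != MISSING

        def allele_counts(mask):
            counts = [0, 0, 0]
            sub = col[mask & ok]
            for code, label in enumerate(v.levels):
                counts[int(label)] = int((sub == code).sum())
            minor = 2 * counts[2] + counts[1]
            major = 2 * counts[0] + counts[1]
            return minor, major, counts

        ca_min, ca_maj, ca_geno = allele_counts(case_mask)
        ct_min, ct_maj, ct_geno = allele_counts(~case_mask)
        row = {"snp": v.name}
        try:
            res = allele_association_test(
                ContingencyTable2x2(ca_min, ca_maj, ct_min, ct_maj)
            )
            row.update(
                allele_chi2=res.chi2, allele_p=res.p, odds_ratio=res.odds_ratio,
                ci_low=res.ci_low, ci_high=res.ci_high,
                bonferroni_significant=res.p < threshold,
            )
        except ValueError:
            row.update(allele_chi2=np.nan, allele_p=np.nan, odds_ratio=np.nan,
                       ci_low=np.nan, ci_high=np.nan, bonferroni_significant=False)
        try:
            g = genotype_association_test(ca_geno, ct_geno)
            row.update(genotype_chi2=g.chi2, genotype_p=g.p, genotype_df=g.df)
        except ValueError:
            row.update(genotype_chi2=np.nan, genotype_p=np.nan, genotype_df=0)
        rows.append(row)
    return pd.DataFrame(rows).set_index("snp")
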