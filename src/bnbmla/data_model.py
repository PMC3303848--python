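"""Discrete genotype/phenotype tables.

The analysis operates on complete tables of categorical variables: SNP
genotypes coded as minor-allele counts (0/1/2), binary phenotypes, and
discretized clinical measurements.  Each variable carries an arity (number
of observed categories), a role (predictor or target) and a kind
(genotype/phenotype/covariate).  Cells are stored as dense integer codes
``0..arity-1``; the original labels are kept per variable so that QC
statistics (which need the 0/1/2 genotype semantics) can map codes back.

Missing cells are represented internally by :data:`MISSING` (-1).  The
Bayesian score assumes a complete dataset, so analysis entry points require
:func:`complete_case_filter` to have been applied first.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel code for a missing cell.
MISSING = -1

_ROLES = ("predictor", "target")
_KINDS = ("genotype", "phenotype", "covariate")


@dataclass(frozen=True)
class VariableMeta:
    """Metadata for one categorical variable.

    ``levels`` maps dense codes back to the original labels, e.g. a SNP
    observed only as homozygote classes has codes ``{0,1}`` with levels
    ``(0, 2)``.
    """

    name: str
    arity: int
    role: str = "predictor"
    kind: str = "genotype"
    levels: tuple = ()

    def __post_init__(self):
        if self.arity < 1:
            raise ValueError(f"arity must be >= 1, got {self.arity} for {self.name!r}")
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.kind not in _KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")


class DiscreteDataset:
    """A table of categorical codes, one row per individual.

    Parameters
    ----------
    variables:
        Ordered metadata, one entry per column.
    codes:
        Integer matrix ``(n_rows, n_vars)``; ``MISSING`` marks absent cells.
    """

    def __init__(self, variables: Sequence[VariableMeta], codes: np.ndarray):
        codes = np.asarray(codes, dtype=np.int16)
        if codes.ndim != 2 or codes.shape[1] != len(variables):
            raise ValueError("codes must be (n_rows, n_vars)")
        names = [v.name for v in variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        for j, v in enumerate(variables):
            col = codes[:, j]
            obs = col[col != MISSING]
            if obs.size and (obs.min() < 0 or obs.max() >= v.arity):
                raise ValueError(f"code out of range for variable {v.name!r}")
        self.variables = list(variables)
        self.codes = codes
        self._index = {n: i for i, n in enumerate(names)}

    # -- basic accessors ---------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.codes.shape[0]

    @property
    def n_vars(self) -> int:
        return self.codes.shape[1]

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def arities(self) -> np.ndarray:
        return np.array([v.arity for v in self.variables], dtype=np.int64)

    @property
    def target_names(self) -> list[str]:
        return [v.name for v in self.variables if v.role == "target"]

    @property
    def predictor_names(self) -> list[str]:
        return [v.name for v in self.variables if v.role == "predictor"]

    def index(self, name: str) -> int:
        return self._index[name]

    def column(self, name: str) -> np.ndarray:
        return self.codes[:, self._index[name]]

    def meta(self, name: str) -> VariableMeta:
        return self.variables[self._index[name]]

    @property
    def is_complete(self) -> bool:
        return not (self.codes == MISSING).any()

    def require_complete(self) -> None:
        if not self.is_complete:
            raise ValueError(
                "dataset contains missing cells; apply complete_case_filter first"
            )

    def call_rates(self) -> dict[str, float]:
        """Fraction of non-missing cells per variable."""
        ok = (self.codes != MISSING).mean(axis=0)
        return {v.name: float(r) for v, r in zip(self.variables, ok)}

    def genotype_counts(self, name: str) -> tuple[int, int, int]:
        """Counts of the original genotype classes (0, 1, 2 minor alleles).

        Uses the variable's level labels, so a SNP with an absent class
        still reports a zero for it.
        """
        v = self.meta(name)
        col = self.column(name)
        counts = [0, 0, 0]
        for code, label in enumerate(v.levels):
            counts[int(label)] = int((col == code).sum())
        return tuple(counts)

    def subset_columns(self, names: Iterable[str]) -> "DiscreteDataset":
        idx = [self._index[n] for n in names]
        return DiscreteDataset([self.variables[i] for i in idx], self.codes[:, idx])

    def to_frame(self, decode: bool = True) -> pd.DataFrame:
        """Export as a DataFrame; ``decode=True`` writes original labels."""
        out = {}
        for j, v in enumerate(self.variables):
            col = self.codes[:, j]
            if decode and v.levels:
                lut = np.asarray(v.levels)
                vals = np.where(col == MISSING, np.nan, lut[np.clip(col, 0, None)])
            else:
                vals = np.where(col == MISSING, np.nan, col).astype(float)
            out[v.name] = vals
        return pd.DataFrame(out)

    def __repr__(self):
        return (
            f"DiscreteDataset(n_rows={self.n_rows}, n_vars={self.n_vars}, "
            f"targets={self.target_names})"
        )


def _encode_column(values: np.ndarray) -> tuple[np.ndarray, tuple]:
    """Map observed values to dense codes 0..k-1 (sorted label order)."""
    mask = ~np.isnan(values)
    levels = np.unique(values[mask])
    codes = np.full(values.shape, MISSING, dtype=np.int16)
    if levels.size:
        codes[mask] = np.searchsorted(levels, values[mask])
    labels = tuple(int(l) if float(l).is_integer() else float(l) for l in levels)
    return codes, labels


def dataset_from_frame(
    frame: pd.DataFrame,
    target_names: Sequence[str] = (),
    kinds: dict[str, str] | None = None,
) -> DiscreteDataset:
    """Build a dataset from a DataFrame of (possibly missing) category labels."""
    kinds = kinds or {}
    target_set = set(target_names)
    unknown = target_set - set(frame.columns)
    if unknown:
        raise KeyError(f"unknown target name(s): {sorted(unknown)}")
    variables, columns = [], []
    for name in frame.columns:
        vals = pd.to_numeric(frame[name], errors="coerce").to_numpy(dtype=float)
        raw = frame[name]
        bad = raw.notna() & np.isnan(vals)
        if bad.any():
            raise ValueError(f"non-categorical cell in column {name!r}")
        noninteger = ~np.isnan(vals) & (np.mod(vals, 1) != 0)
        if noninteger.any():
            raise ValueError(f"non-categorical cell in column {name!r}")
        codes, levels = _encode_column(vals)
        role = "target" if name in target_set else "predictor"
        kind = kinds.get(name, "phenotype" if role == "target" else "genotype")
        variables.append(
            VariableMeta(name, max(len(levels), 1), role=role, kind=kind, levels=levels)
        )
        columns.append(codes)
    return DiscreteDataset(variables, np.column_stack(columns))


def load_genotype_table(
    path: str | Path,
    target_names: Sequence[str] = (),
    dialect: str = "auto",
) -> DiscreteDataset:
    """Read a delimited genotype/phenotype table.

    Header row gives variable names; genotype cells are minor-allele counts
    in {0,1,2} or a missing marker (empty, NA, .).  Missing cells are kept
    (flagged for the downstream complete-case policy) and call rates are
    logged.
    """
    path = Path(path)
    sep = {"csv": ",", "tsv": "\t", "auto": None}.get(dialect, dialect)
    with open(path) as fh:
        header = fh.readline()
    delim = sep or ("\t" if "\t" in header else ",")
    raw_names = [h.strip() for h in header.rstrip("\n").split(delim)]
    dupes = {n for n in raw_names if raw_names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate column names: {sorted(dupes)}")
    frame = pd.read_csv(path, sep=delim, na_values=["NA", "na", ".", ""])
    ds = dataset_from_frame(frame, target_names=target_names)
    rates = ds.call_rates()
    n_missing = int((ds.codes == MISSING).sum())
    mono = [v.name for v in ds.variables if v.arity == 1]
    logger.info(
        "loaded %s: %d rows x %d columns, %d missing cells, %d monomorphic",
        path.name, ds.n_rows, ds.n_vars, n_missing, len(mono),
    )
    if n_missing:
        low = {k: round(v, 3) for k, v in rates.items() if v < 1.0}
        logger.info("call rates below 1.0: %s", low)
    return ds


def load_vcf(path: str | Path) -> DiscreteDataset:
    """Import biallelic genotypes from a VCF as alt-allele counts 0/1/2.

    Multi-allelic records are skipped with a warning; phase is ignored
    (``0|1`` and ``0/1`` both code 1).  Sample order is preserved.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError("VCF contains no samples")
    names, columns = [], []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_skipped += 1
            continue
        col = np.full(len(samples), MISSING, dtype=np.int16)
        for i, gt in enumerate(variant.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if len(alleles) == 2:
                col[i] = sum(alleles)
        name = variant.ID or f"{variant.CHROM}:{variant.POS}"
        names.append(name)
        columns.append(col)
    if n_skipped:
        logger.warning("skipped %d multi-allelic record(s)", n_skipped)
    if not names:
        raise ValueError("no biallelic records in VCF")
    frame = pd.DataFrame(
        {n: np.where(c == MISSING, np.nan, c) for n, c in zip(names, columns)}
    )
    ds = dataset_from_frame(frame)
    logger.info("loaded VCF %s: %d samples, %d sites", path, ds.n_rows, ds.n_vars)
    return ds


def discretize_continuous(
    values: Sequence[float],
    scheme: str = "median",
    cutpoints: Sequence[float] | None = None,
) -> tuple[np.ndarray, tuple[float, ...]]:
    """Discretize a numeric vector into ordinal codes.

    Schemes: ``median`` (2 bins), ``tertile`` (3 bins, rank-based), or
    ``fixed_cutpoints`` (caller-provided).  Ties go to the lower bin, i.e.
    code = number of cutpoints strictly below the value.
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if np.unique(x).size < 2:
        raise ValueError("all values identical; nothing to discretize")
    if scheme == "median":
        cuts = (float(np.median(x)),)
    elif scheme == "tertile":
        cuts = tuple(float(c) for c in np.quantile(x, [1 / 3, 2 / 3]))
    elif scheme == "fixed_cutpoints":
        if not cutpoints:
            raise ValueError("fixed_cutpoints scheme needs cutpoints")
        cuts = tuple(sorted(float(c) for c in cutpoints))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    codes = np.zeros(x.shape, dtype=np.int16)
    for c in cuts:
        codes += (x > c).astype(np.int16)
    return codes, cuts


def complete_case_filter(
    dataset: DiscreteDataset, policy: str = "drop_rows"
) -> tuple[DiscreteDataset, dict]:
    """Resolve missing cells so the closed-form score's completeness holds.

    ``drop_rows`` removes every row with at least one missing cell;
    ``mode_impute`` fills each missing cell with the variable's most
    frequent observed code.  Codes are re-compacted afterwards so each
    variable's arity equals its number of observed categories.
    """
    codes = dataset.codes
    missing = codes == MISSING
    report = {
        "policy": policy,
        "rows_removed": 0,
        "cells_imputed": 0,
        "rows_in": dataset.n_rows,
    }
    if policy == "drop_rows":
        keep = ~missing.any(axis=1)
        report["rows_removed"] = int((~keep).sum())
        new_codes = codes[keep]
        if new_codes.shape[0] == 0:
            raise ValueError("drop_rows removed every row")
    elif policy == "mode_impute":
        new_codes = codes.copy()
        for j, v in enumerate(dataset.variables):
            col = new_codes[:, j]
            miss = col == MISSING
            if miss.any():
                obs = col[~miss]
                if obs.size == 0:
                    raise ValueError(f"variable {v.name!r} entirely missing")
                mode = int(np.bincount(obs).argmax())
                col[miss] = mode
                report["cells_imputed"] += int(miss.sum())
    else:
        raise ValueError(f"unknown policy {policy!r}")
    # re-compact: categories may vanish when rows are dropped
    variables, cols = [], []
    for j, v in enumerate(dataset.variables):
        col = new_codes[:, j].astype(float)
        lut = np.asarray(v.levels if v.levels else range(v.arity), dtype=float)
        decoded = lut[new_codes[:, j]]
        dense, labels = _encode_column(decoded)
        variables.append(replace(v, arity=max(len(labels), 1), levels=labels))
        cols.append(dense)
    out = DiscreteDataset(variables, np.column_stack(cols))
    report["rows_out"] = out.n_rows
    return out, report


# -- persistence ----------------------------------------------------------

def save_dataset(dataset: DiscreteDataset, path: str | Path, sep: str = ",") -> None:
    """Write codes as delimited text plus a JSON sidecar with the metadata."""
    path = Path(path)
    frame = pd.DataFrame(
        {v.name: dataset.codes[:, j] for j, v in enumerate(dataset.variables)}
    )
    frame.replace(MISSING, np.nan).to_csv(path, sep=sep, index=False)
    meta = [
        {
            "name": v.name,
            "arity": v.arity,
            "role": v.role,
            "kind": v.kind,
            "levels": list(v.levels),
        }
        for v in dataset.variables
    ]
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def load_dataset(path: str | Path, sep: str = ",") -> DiscreteDataset:
    """Inverse of :func:`save_dataset`; reproduces codes exactly."""
    path = Path(path)
    frame = pd.read_csv(path, sep=sep)
    meta = json.loads(Path(str(path) + ".meta.json").read_text())
    variables, cols = [], []
    for m in meta:
        v = VariableMeta(
            m["name"], m["arity"], role=m["role"], kind=m["kind"],
            levels=tuple(m["levels"]),
        )
        raw = frame[m["name"]].to_numpy(dtype=float)
        codes = np.where(np.isnan(raw), MISSING, raw).astype(np.int16)
        variables.append(v)
        cols.append(codes)
    return DiscreteDataset(variables, np.column_stack(cols))
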