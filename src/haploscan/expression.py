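"""Relative qPCR quantification (2^-ddCt) and phenotype-expression trends.

The comparative threshold-cycle method: a target gene's Ct is normalized
against reference genes to give dCt; subtracting the control condition's
dCt gives ddCt; the fold change of the treated relative to the control
condition is 2^-ddCt.  Reference normalization here follows the geometric
mean of the reference genes' Ct values (with the arithmetic-mean variant —
equivalent to the geometric mean of their expression levels — behind a
switch; the two differ only when the reference Cts diverge).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class FoldChange:
    """ddCt and the corresponding fold change 2^-ddCt."""

    delta_ct_treated: float
    delta_ct_control: float

    @property
    def delta_delta_ct(self) -> float:
        return self.delta_ct_treated - self.delta_ct_control

    @property
    def fold(self) -> float:
        return float(2.0 ** (-self.delta_delta_ct))


def normalize_ct(
    table: pd.DataFrame,
    reference_genes: Sequence[str] = ("GAPDH", "18S"),
    method: str = "geometric_ct",
) -> pd.DataFrame:
    """dCt per (line, condition, target gene).

    Replicate Cts are averaged per gene first; the reference value is the
    geometric mean of the reference genes' mean Cts (``geometric_ct``,
    the literal reading) or their arithmetic mean (``arithmetic_ct``).
    dCt = target mean Ct - reference value.
    """
    if method not in ("geometric_ct", "arithmetic_ct"):
        raise ValueError(f"unknown normalization method {method!r}")
    means = (
        table.groupby(["line", "condition", "gene"], sort=False)["ct"].mean().reset_index()
    )
    rows = []
    for (line, condition), grp in means.groupby(["line", "condition"], sort=False):
        by_gene = dict(zip(grp["gene"], grp["ct"]))
        missing = [g for g in reference_genes if g not in by_gene]
        if missing:
            raise ValueError(
                f"reference gene(s) {missing} missing for line {line!r}, condition {condition!r}"
            )
        refs = np.array([by_gene[g] for g in reference_genes], dtype=float)
        ref_value = float(stats.gmean(refs)) if method == "geometric_ct" else float(refs.mean())
        for gene, ct in by_gene.items():
            if gene in reference_genes:
                continue
            rows.append(
                {
                    "line": line,
                    "condition": condition,
                    "gene": gene,
                    "delta_ct": float(ct) - ref_value,
                }
            )
    return pd.DataFrame(rows)


def delta_delta_ct(dct_treated: float, dct_control: float) -> FoldChange:
    """ddCt = treated dCt - control dCt; fold change = 2^-ddCt."""
    return FoldChange(delta_ct_treated=float(dct_treated), delta_ct_control=float(dct_control))


def fold_changes(
    table: pd.DataFrame,
    reference_genes: Sequence[str] = ("GAPDH", "18S"),
    treated: str = "knockdown",
    control: str = "scramble",
    method: str = "geometric_ct",
) -> pd.DataFrame:
    """Per-line, per-target fold changes of ``treated`` relative to ``control``."""
    dct = normalize_ct(table, reference_genes=reference_genes, method=method)
    wide = dct.pivot_table(
        index=["line", "gene"], columns="condition", values="delta_ct", aggfunc="first"
    )
    if treated not in wide.columns or control not in wide.columns:
        raise ValueError(f"conditions {treated!r}/{control!r} not both present")
    rows = []
    for (line, gene), r in wide.iterrows():
        fc = delta_delta_ct(r[treated], r[control])
        rows.append(
            {
                "line": line,
                "gene": gene,
                "delta_ct_treated": fc.delta_ct_treated,
                "delta_ct_control": fc.delta_ct_control,
                "delta_delta_ct": fc.delta_delta_ct,
                "fold": fc.fold,
            }
        )
    return pd.DataFrame(rows)


def phenotype_bin(z: float) -> int:
    """Ordinal deficit score from a phonological-coding z-score.

    0 for z >= -1.0; 1 for -2.0 <= z < -1.0; 2 for -3.0 <= z < -2.0;
    3 for z < -3.0.  Higher scores mean a more severe deficit.
    """
    if z >= -1.0:
        return 0
    if z >= -2.0:
        return 1
    if z >= -3.0:
        return 2
    return 3


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float

    @property
    def direction(self) -> str:
        return "positive" if self.r > 0 else "negative" if self.r < 0 else "flat"


def fold_regression(x_folds: Sequence[float], y_folds: Sequence[float]) -> RegressionResult:
    """OLS regression of one gene's fold changes on another's."""
    x = np.asarray(x_folds, dtype=float)
    y = np.asarray(y_folds, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 paired fold changes")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in x fold changes")
    fit = stats.linregress(x, y)
    return RegressionResult(slope=float(fit.slope), intercept=float(fit.intercept), r=float(fit.rvalue))


@dataclass(frozen=True)
class TrendResult:
    """Rank correlation with a seeded permutation null interval."""

    rho: float
    direction: str
    null_lower: float
    null_upper: float
    n_permutations: int
    seed: int

    @property
    def outside_null(self) -> bool:
        return not (self.null_lower <= self.rho <= self.null_upper)


def expression_phenotype_trend(
    records: pd.DataFrame,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> TrendResult:
    """Spearman correlation between expression and ordinal deficit score.

    A negative rho means lower expression accompanies a more severe
    deficit.  The null interval is the central 95% of rho under random
    permutation of the expression values (seeded).  Constant input is
    flagged as an undefined trend.
    """
    expr = np.asarray(records["expression"], dtype=float)
    score = np.asarray(records["score"], dtype=float)
    if np.allclose(expr, expr[0]) or np.allclose(score, score[0]):
        return TrendResult(
            rho=float("nan"), direction="undefined", null_lower=float("nan"),
            null_upper=float("nan"), n_permutations=0, seed=seed,
        )
    rho = float(stats.spearmanr(expr, score).statistic)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = stats.spearmanr(rng.permutation(expr), score).statistic
    lo, hi = np.quantile(null, [0.025, 0.975])
    direction = "negative" if rho < 0 else "positive" if rho > 0 else "flat"
    return TrendResult(
        rho=rho, direction=direction, null_lower=float(lo), null_upper=float(hi),
        n_permutations=n_permutations, seed=seed,
    )
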