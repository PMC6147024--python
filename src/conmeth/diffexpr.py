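"""Two-group differential expression on FPKM matrices.

The DEG rule combines an FDR-adjusted two-sample test on log2(FPKM + eps)
with a fold-change threshold on group means of raw FPKM:
a gene is differentially expressed iff q < 0.05 (strict) and
|log2((mean_B + eps)/(mean_A + eps))| >= 2 (inclusive).  The default test
is Welch's t, a robust choice at n = 6 per group.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .diffmeth import StudyDesign

logger = logging.getLogger(__name__)


def load_expression(path: str | Path) -> pd.DataFrame:
    """Genes x samples FPKM matrix from TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy(dtype=float) < 0).any():
        raise ValueError("negative FPKM values")
    return df


class DifferentialExpression:
    """Two-group differential-expression model on an FPKM matrix.

    Parameters
    ----------
    expr : DataFrame
        Genes x samples, FPKM >= 0; columns must cover the design samples.
    design : StudyDesign
        Two-group assignment; lfc = log2((mean_B + eps) / (mean_A + eps)).
    """

    def __init__(self, expr: pd.DataFrame, design: StudyDesign):
        missing = set(design.samples) - set(expr.columns)
        if missing:
            raise ValueError(f"design samples missing from matrix: {sorted(missing)}")
        if (expr[design.samples].to_numpy(dtype=float) < 0).any():
            raise ValueError("negative FPKM values")
        self.expr = expr[design.samples]
        self.design = design

    def fit(
        self, alpha: float = 0.05, min_lfc: float = 2.0, eps: float = 1.0
    ) -> "DEGResults":
        x = self.expr.to_numpy(dtype=float)
        nonzero = x.sum(axis=1) > 0
        n_allzero = int((~nonzero).sum())
        if n_allzero:
            logger.info("excluded %d all-zero genes", n_allzero)
        expr = self.expr.loc[nonzero]
        x = x[nonzero]

        ga, gb = self.design.groups
        ia = [expr.columns.get_loc(s) for s in self.design.samples_of(ga)]
        ib = [expr.columns.get_loc(s) for s in self.design.samples_of(gb)]
        la = np.log2(x[:, ia] + eps)
        lb = np.log2(x[:, ib] + eps)

        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = scipy.stats.ttest_ind(lb, la, axis=1, equal_var=False)
        # genes constant across all samples carry no evidence
        constant = np.all(x == x[:, [0]], axis=1)
        p = np.where(constant, 1.0, p)
        p = np.where(np.isnan(p), 1.0, p)

        mean_a = x[:, ia].mean(axis=1)
        mean_b = x[:, ib].mean(axis=1)
        lfc = np.log2((mean_b + eps) / (mean_a + eps))
        q = multipletests(p, method="fdr_bh")[1]

        table = pd.DataFrame(
            {
                "mean_a": mean_a,
                "mean_b": mean_b,
                "lfc": lfc,
                "p": p,
                "q": q,
            },
            index=expr.index,
        )
        table["is_deg"] = (table["q"] < alpha) & (table["lfc"].abs() >= min_lfc)
        table["direction"] = np.where(table["lfc"] >= 0, "up", "down")
        return DEGResults(
            table=table,
            alpha=alpha,
            min_lfc=min_lfc,
            eps=eps,
            design=self.design,
            n_allzero=n_allzero,
        )


class DEGResults:
    """Results of a DifferentialExpression fit."""

    def __init__(
        self,
        table: pd.DataFrame,
        alpha: float,
        min_lfc: float,
        eps: float,
        design: StudyDesign,
        n_allzero: int,
    ):
        self.table = table
        self.alpha = alpha
        self.min_lfc = min_lfc
        self.eps = eps
        self.design = design
        self.n_allzero = n_allzero

    @property
    def degs(self) -> pd.DataFrame:
        return self.table[self.table["is_deg"]]

    @property
    def n_deg(self) -> int:
        return int(self.table["is_deg"].sum())

    @property
    def n_up(self) -> int:
        d = self.degs
        return int((d["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        d = self.degs
        return int((d["direction"] == "down").sum())

    def summary(self) -> str:
        ga, gb = self.design.groups
        return "\n".join(
            [
                "Differential expression (Welch t on log2 FPKM)",
                "=" * 46,
                f"groups:          {ga} (A, reference) vs {gb} (B)",
                f"genes tested:    {len(self.table)}",
                f"all-zero genes:  {self.n_allzero}",
                f"thresholds:      q < {self.alpha}, |lfc| >= {self.min_lfc}, eps = {self.eps}",
                f"DEGs called:     {self.n_deg} ({self.n_down} down, {self.n_up} up in {gb})",
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


def call_degs(
    expr: pd.DataFrame,
    design: StudyDesign,
    alpha: float = 0.05,
    min_lfc: float = 2.0,
    eps: float = 1.0,
) -> DEGResults:
    """Functional wrapper over DifferentialExpression.fit."""
    return DifferentialExpression(expr, design).fit(alpha=alpha, min_lfc=min_lfc, eps=eps)


class ScaledMatrix:
    """A row-scaled expression matrix for heatmap export."""

    def __init__(self, data: pd.DataFrame, mode: str, zero_variance_rows: list[str]):
        self.data = data
        self.mode = mode
        self.zero_variance_rows = zero_variance_rows

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene_id")


def scale_matrix(
    expr: pd.DataFrame, mode: str = "mean_centered_log2", eps: float = 1.0
) -> ScaledMatrix:
    """Row-scale an FPKM matrix for heatmap display.

    ``mean_centered_log2`` subtracts the row mean of log2(FPKM + eps);
    ``zscore`` additionally divides by the row standard deviation (sample
    sd, ddof=1).  Zero-variance rows become all zeros and are flagged.
    """
    if mode not in ("mean_centered_log2", "zscore"):
        raise ValueError(f"unknown scaling mode {mode!r}")
    logx = np.log2(expr.to_numpy(dtype=float) + eps)
    if not np.isfinite(logx).all():
        raise ValueError("matrix not finite after log transform")
    centered = logx - logx.mean(axis=1, keepdims=True)
    flagged: list[str] = []
    if mode == "zscore":
        sd = logx.std(axis=1, ddof=1)
        zero = sd == 0
        flagged = list(expr.index[zero])
        centered = np.where(zero[:, None], 0.0, centered / np.where(zero, 1.0, sd)[:, None])
    out = pd.DataFrame(centered, index=expr.index, columns=expr.columns)
    return ScaledMatrix(out, mode, flagged)


def ora(
    selected: set[str] | Sequence[str],
    annotated: set[str] | Sequence[str],
    universe: set[str] | Sequence[str],
) -> tuple[int, float, float]:
    """Over-representation of an annotated set within a selection.

    Upper-tail hypergeometric: with population N = |universe|, successes
    K = |annotated|, draws n = |selected|, returns (k, P(X >= k), fold
    enrichment (k/n)/(K/N)).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected)
    annotated = set(annotated)
    if not selected <= universe or not annotated <= universe:
        raise ValueError("selected and annotated must be subsets of the universe")
    N, K, n = len(universe), len(annotated), len(selected)
    k = len(selected & annotated)
    p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n))
    expected = K * n / N
    fold = (k / expected) if expected > 0 else math.nan
    return k, p, fold


def ora_collection(
    selected: set[str] | Sequence[str],
    gene_sets: Mapping[str, set[str] | Sequence[str]],
    universe: set[str] | Sequence[str],
) -> pd.DataFrame:
    """Apply :func:`ora` across a collection of sets with BH adjustment."""
    rows = []
    for name, annotated in gene_sets.items():
        k, p, fold = ora(selected, set(annotated) & set(universe), universe)
        rows.append({"set": name, "overlap": k, "p": p, "fold": fold})
    out = pd.DataFrame(rows).set_index("set")
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene-set file: name, description, members..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets
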