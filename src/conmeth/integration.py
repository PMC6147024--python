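"""Methylation-expression integration.

Joins differentially methylated fragments with differentially expressed
genes by genomic context (promoter, gene body, linked enhancer), computes
Spearman correlations of genes against an anchor gene (e.g. *CD274*) and
against the per-sample global methylation summary, builds regulator
correlograms, restricts expression matrices to gene panels, and provides
the background-subtracted flow-cytometry MFI log2 fold-change formula.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from intervaltree import IntervalTree

from .annotation import GeneTable, PROMOTER_DOWNSTREAM, PROMOTER_UPSTREAM
from .diffexpr import ScaledMatrix, scale_matrix

logger = logging.getLogger(__name__)

#: below this sample count the Spearman p value is computed by exact
#: permutation enumeration rather than the t approximation
EXACT_PERMUTATION_N = 10


@dataclass(frozen=True)
class CorrelationResult:
    x: str
    y: str
    rho: float
    p: float
    n: int


def _rank_pearson(x: np.ndarray, y: np.ndarray) -> float:
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(
    x: Sequence[float], y: Sequence[float], x_name: str = "x", y_name: str = "y"
) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    The p value uses the t approximation for n >= 10 and exact permutation
    enumeration (two-sided, on |rho|) below that; n >= 3 is required for a
    p value at all.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("at least 3 samples required")
    rho = _rank_pearson(x, y)
    if np.isnan(rho):
        return CorrelationResult(x_name, y_name, float("nan"), float("nan"), n)
    if n >= EXACT_PERMUTATION_N:
        p = float(scipy.stats.spearmanr(x, y).pvalue)
    else:
        ry = scipy.stats.rankdata(y)
        rx = scipy.stats.rankdata(x)
        target = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            if abs(r) >= target - 1e-12:
                count += 1
            total += 1
        p = count / total
    return CorrelationResult(x_name, y_name, float(rho), p, n)


def correlate_genes(
    expr: pd.DataFrame,
    anchor_gene: str,
    global_meth: pd.Series,
) -> pd.DataFrame:
    """Per-gene Spearman against the anchor gene and the methylome summary.

    ``global_meth`` is the per-sample global methylation statistic
    (median fragment methylation).  Returns one row per non-anchor gene
    with rho/p against both targets; used for heatmap correlation sidebars.
    """
    if anchor_gene not in expr.index:
        raise ValueError(f"anchor gene {anchor_gene!r} absent from matrix")
    common = [s for s in expr.columns if s in global_meth.index]
    if len(common) < 3:
        raise ValueError("fewer than 3 common samples")
    anchor = expr.loc[anchor_gene, common].to_numpy(dtype=float)
    meth = global_meth[common].to_numpy(dtype=float)
    rows = []
    for gene in expr.index:
        if gene == anchor_gene:
            continue
        vals = expr.loc[gene, common].to_numpy(dtype=float)
        ra = spearman(vals, anchor, gene, anchor_gene)
        rm = spearman(vals, meth, gene, "global_methylation")
        rows.append(
            {
                "gene": gene,
                "rho_anchor": ra.rho,
                "p_anchor": ra.p,
                "rho_methylome": rm.rho,
                "p_methylome": rm.p,
                "n": ra.n,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


DEFAULT_REGULATORS = (
    "DNMT1",
    "DNMT3A",
    "DNMT3B",
    "UHRF1",
    "UHRF2",
    "TET1",
    "TET2",
    "TET3",
    "APOBEC3F",
    "APOBEC3G",
)


def load_gene_list(name: str) -> list[str]:
    """Read a bundled gene list (one symbol per line, '#' comments)."""
    text = resources.files("conmeth.data").joinpath(name).read_text()
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]


class Correlogram:
    """Symmetric Spearman matrix over regulators, anchor and methylome."""

    def __init__(self, rho: pd.DataFrame, p: pd.DataFrame, n: int):
        self.rho = rho
        self.p = p
        self.n = n

    def to_tsv(self, path: str | Path) -> None:
        self.rho.to_csv(path, sep="\t", index_label="variable")

    def to_dict(self) -> dict:
        return {
            "variables": list(self.rho.index),
            "rho": self.rho.to_numpy().tolist(),
            "p": self.p.to_numpy().tolist(),
            "n": self.n,
        }


def regulator_correlogram(
    expr: pd.DataFrame,
    regulators: Sequence[str] | None = None,
    anchor_gene: str = "CD274",
    global_meth: pd.Series | None = None,
) -> Correlogram:
    """Cross-correlation of epigenetic-regulator expression, anchor-gene
    expression and global methylation.

    The default regulator panel covers the DNA methylation machinery:
    maintenance (DNMT1) and de novo (DNMT3A/B) methyltransferases, their
    UHRF1/2 modulators, the TET demethylases and APOBEC3F/G deaminases.
    Regulators missing from the matrix are dropped with a warning.
    """
    if regulators is None:
        regulators = list(DEFAULT_REGULATORS)
    missing = [g for g in regulators if g not in expr.index]
    if missing:
        warnings.warn(f"regulators absent from matrix, dropped: {missing}")
    regs = [g for g in regulators if g in expr.index]

    samples = list(expr.columns)
    variables: dict[str, np.ndarray] = {}
    for g in regs:
        variables[g] = expr.loc[g, samples].to_numpy(dtype=float)
    if anchor_gene is not None:
        if anchor_gene not in expr.index:
            raise ValueError(f"anchor gene {anchor_gene!r} absent from matrix")
        if anchor_gene not in variables:
            variables[anchor_gene] = expr.loc[anchor_gene, samples].to_numpy(dtype=float)
    if global_meth is not None:
        variables["global_methylation"] = global_meth[samples].to_numpy(dtype=float)
    names = list(variables)
    k = len(names)
    rho = np.eye(k)
    pmat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            res = spearman(variables[names[i]], variables[names[j]], names[i], names[j])
            rho[i, j] = rho[j, i] = res.rho
            pmat[i, j] = pmat[j, i] = res.p
    return Correlogram(
        pd.DataFrame(rho, index=names, columns=names),
        pd.DataFrame(pmat, index=names, columns=names),
        n=len(samples),
    )


# ---------------------------------------------------------------------------
# DMF x DEG integration
# ---------------------------------------------------------------------------


def read_enhancers(path: str | Path) -> pd.DataFrame:
    """Enhancer BED (0-based half-open) with the linked gene id in column 4."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 4 or not f[3]:
                raise ValueError(f"{path}:{lineno}: enhancer interval without gene link")
            rows.append((f[0], int(f[1]), int(f[2]), f[3]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def integrate_dmf_deg(
    dmfs: pd.DataFrame,
    degs: pd.DataFrame,
    genes: GeneTable,
    enhancers: pd.DataFrame | None = None,
    promoter_upstream: int = PROMOTER_UPSTREAM,
    promoter_downstream: int = PROMOTER_DOWNSTREAM,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attribute DMFs to DEGs by genomic context.

    For each DEG, overlapping DMFs are looked up in the gene's own
    promoter window (TSS -5 kb/+1 kb, strand-aware), gene body (transcript
    span minus the promoter window) and, when supplied, enhancer intervals
    linked to the gene.  A DMF overlapping two genes is attributed to both,
    each in its own context.  Returns (records, concordance) where records
    has one row per gene-DMF-context hit and concordance cross-tabulates
    context x methylation direction x expression direction.  Genes with
    two or more DMFs are flagged ``multi_dmf``.

    ``dmfs`` must carry chrom/start/end columns (as written by
    DMFResults.to_tsv) or a ``chrom:start-end`` index; only rows with
    ``is_dmf`` true are used.  ``degs`` is the DEG-only table indexed by
    gene id with ``lfc`` and ``direction`` columns.
    """
    dmf = dmfs[dmfs["is_dmf"]].copy() if "is_dmf" in dmfs.columns else dmfs.copy()
    if not {"chrom", "start", "end"}.issubset(dmf.columns):
        coords = dmf.index.to_series().str.extract(
            r"(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)"
        )
        dmf[["chrom", "start", "end"]] = coords
    dmf["start"] = dmf["start"].astype(int)
    dmf["end"] = dmf["end"].astype(int)

    if enhancers is not None:
        if "gene_id" not in enhancers.columns or enhancers["gene_id"].isna().any():
            raise ValueError("enhancer intervals must carry gene links")

    trees: dict[str, IntervalTree] = {}
    for i, row in enumerate(dmf.itertuples(index=True)):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row.Index)

    def overlapping(chrom: str, lo: int, hi: int) -> list[str]:
        if lo >= hi or chrom not in trees:
            return []
        return [iv.data for iv in trees[chrom].overlap(lo, hi)]

    records = []
    for gene_id in degs.index:
        if gene_id not in genes:
            continue
        g = genes[gene_id]
        p_lo, p_hi = g.promoter(None, promoter_upstream, promoter_downstream)
        contexts: list[tuple[str, str]] = []
        for frag in overlapping(g.chrom, p_lo, p_hi):
            contexts.append(("promoter", frag))
        # gene body = transcript span minus the promoter window
        for b_lo, b_hi in _span_minus(g.tx_start, g.tx_end, p_lo, p_hi):
            for frag in overlapping(g.chrom, b_lo, b_hi):
                contexts.append(("gene_body", frag))
        if enhancers is not None:
            linked = enhancers[enhancers["gene_id"] == gene_id]
            for erow in linked.itertuples(index=False):
                for frag in overlapping(erow.chrom, erow.start, erow.end):
                    contexts.append(("enhancer", frag))
        seen = set()
        for context, frag in contexts:
            if (context, frag) in seen:
                continue
            seen.add((context, frag))
            drow = dmf.loc[frag]
            meth_dir = drow["direction"] if "direction" in drow else (
                "hypo" if drow["diff"] < 0 else "hyper"
            )
            expr_dir = degs.loc[gene_id, "direction"]
            records.append(
                {
                    "gene": gene_id,
                    "lfc": float(degs.loc[gene_id, "lfc"]),
                    "expr_direction": expr_dir,
                    "fragment": frag,
                    "context": context,
                    "meth_diff": float(drow["diff"]),
                    "meth_direction": meth_dir,
                    "concordance": _concordance(context, meth_dir, expr_dir),
                }
            )
    rec = pd.DataFrame(
        records,
        columns=[
            "gene",
            "lfc",
            "expr_direction",
            "fragment",
            "context",
            "meth_diff",
            "meth_direction",
            "concordance",
        ],
    )
    if len(rec):
        counts = rec.groupby("gene")["fragment"].nunique()
        rec["multi_dmf"] = rec["gene"].map(counts >= 2)
        concordance = (
            rec.groupby(["context", "meth_direction", "expr_direction"])
            .size()
            .rename("n")
            .reset_index()
        )
    else:
        rec["multi_dmf"] = pd.Series(dtype=bool)
        concordance = pd.DataFrame(
            columns=["context", "meth_direction", "expr_direction", "n"]
        )
    return rec, concordance


def _span_minus(
    lo: int, hi: int, cut_lo: int, cut_hi: int
) -> list[tuple[int, int]]:
    """Interval [lo,hi) minus [cut_lo,cut_hi)."""
    out = []
    if cut_lo > lo:
        out.append((lo, min(cut_lo, hi)))
    if cut_hi < hi:
        out.append((max(cut_hi, lo), hi))
    return [(s, e) for s, e in out if s < e]


_CONTEXT_SHORT = {"promoter": "promoter", "gene_body": "body", "enhancer": "enhancer"}


def _concordance(context: str, meth_dir: str, expr_dir: str) -> str:
    return f"{_CONTEXT_SHORT[context]}-{meth_dir}/{expr_dir}"


# ---------------------------------------------------------------------------
# Gene panels and flow cytometry
# ---------------------------------------------------------------------------


def panel_matrix(
    expr: pd.DataFrame,
    panel: Sequence[str] | None = None,
    mode: str = "mean_centered_log2",
    eps: float = 1.0,
) -> tuple[ScaledMatrix, list[str]]:
    """Scale the expression matrix restricted to a gene panel.

    The default panel is the bundled viral-mimicry / immune gene set
    (type-I-interferon-stimulated and dsRNA-sensing genes whose
    de-repression accompanies genomic hypomethylation).  Returns the
    scaled matrix and the list of panel genes missing from the matrix.
    """
    if panel is None:
        panel = load_gene_list("viral_mimicry_panel.txt")
    present = [g for g in panel if g in expr.index]
    missing = [g for g in panel if g not in expr.index]
    if not present:
        raise ValueError("no panel gene present in the expression matrix")
    if missing:
        logger.info("panel genes absent from matrix: %s", missing)
    return scale_matrix(expr.loc[present], mode=mode, eps=eps), missing


@dataclass(frozen=True)
class FlowMeasurement:
    """Median fluorescence intensities for a treated/mock antibody assay."""

    mfi_antibody_treated: float
    mfi_isotype_treated: float
    mfi_antibody_mock: float
    mfi_isotype_mock: float


def mfi_log2fc(m: FlowMeasurement) -> float:
    """Background-subtracted MFI log2 fold change:
    log2((antibody_treated - isotype_treated) / (antibody_mock - isotype_mock)).

    Both background-subtracted differences must be positive; otherwise the
    measurement is unusable and an error is raised.
    """
    num = m.mfi_antibody_treated - m.mfi_isotype_treated
    den = m.mfi_antibody_mock - m.mfi_isotype_mock
    if num <= 0 or den <= 0:
        raise ValueError(
            "background-subtracted MFI differences must be positive "
            f"(got {num} and {den})"
        )
    return float(np.log2(num / den))
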