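"""Two-group differential methylation: global summaries and DMF calling.

The differentially methylated fragment (DMF) test is a one-way ANOVA
(two groups) on per-sample fragment methylation proportions, with
Benjamini-Hochberg adjustment across all tested fragments.  A fragment is
a DMF iff q <= alpha and |mean difference| >= delta (defaults 0.05 and
0.25).  The sign convention is diff = mean(group B) - mean(group A), with
group A the reference (inducible-like) and group B the constitutive-like
group, so group-B hypomethylation appears as negative differences.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .rrbs import FragmentMethMatrix

logger = logging.getLogger(__name__)


class StudyDesign:
    """Sample-to-group assignment for a two-group comparison.

    Group order fixes the sign of all differences: ``groups[0]`` is the
    reference group A, ``groups[1]`` is group B, and every reported
    difference is mean_B - mean_A.
    """

    def __init__(self, assignment: Mapping[str, str], group_order: Sequence[str] | None = None):
        self._assignment = dict(assignment)
        seen: list[str] = []
        for g in self._assignment.values():
            if g not in seen:
                seen.append(g)
        if group_order is None:
            group_order = seen
        group_order = list(group_order)
        if len(group_order) != 2 or set(group_order) != set(seen):
            raise ValueError(
                f"exactly two groups required, got {seen} (order {group_order})"
            )
        self.groups: tuple[str, str] = (group_order[0], group_order[1])
        for g in self.groups:
            if len(self.samples_of(g)) < 2:
                raise ValueError(f"group {g!r} has fewer than 2 samples")

    @property
    def samples(self) -> list[str]:
        return list(self._assignment)

    def group_of(self, sample: str) -> str:
        return self._assignment[sample]

    def samples_of(self, group: str) -> list[str]:
        return [s for s, g in self._assignment.items() if g == group]

    @classmethod
    def from_tsv(cls, path: str | Path, group_order: Sequence[str] | None = None) -> "StudyDesign":
        """Two-column TSV: sample_id, group (header optional)."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        if list(df.columns[:2]) != ["sample_id", "group"]:
            df = pd.read_csv(path, sep="\t", dtype=str, header=None,
                             names=["sample_id", "group"])
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in design")
        return cls(dict(zip(df["sample_id"], df["group"])), group_order)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"sample_id": self.samples,
             "group": [self.group_of(s) for s in self.samples]}
        ).to_csv(path, sep="\t", index=False)


def _anova_two_group(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise one-way ANOVA on two masked groups (NaN = missing).

    Returns (F, p, mean_a, mean_b).  Rows with zero variance within and
    between groups get p = 1 by convention.  Rows with < 2 observations in
    either group get NaN F/p (callers skip them).
    """
    na = np.sum(~np.isnan(a), axis=1)
    nb = np.sum(~np.isnan(b), axis=1)
    with np.errstate(invalid="ignore"):
        ma = np.nanmean(a, axis=1)
        mb = np.nanmean(b, axis=1)
        ssa = np.nansum((a - ma[:, None]) ** 2, axis=1)
        ssb = np.nansum((b - mb[:, None]) ** 2, axis=1)
    n = na + nb
    grand = (na * ma + nb * mb) / n
    ss_between = na * (ma - grand) ** 2 + nb * (mb - grand) ** 2
    ss_within = ssa + ssb
    df_between = 1.0
    df_within = n - 2.0

    F = np.full(a.shape[0], np.nan)
    p = np.full(a.shape[0], np.nan)
    testable = (na >= 2) & (nb >= 2)
    degenerate = testable & (ss_within <= 0) & (ss_between <= 0)
    ok = testable & ~degenerate
    with np.errstate(divide="ignore", invalid="ignore"):
        F[ok] = (ss_between[ok] / df_between) / (ss_within[ok] / df_within[ok])
    p[ok] = scipy.stats.f.sf(F[ok], df_between, df_within[ok])
    # all values identical: no evidence either way
    F[degenerate] = 0.0
    p[degenerate] = 1.0
    n_degenerate = int(degenerate.sum())
    if n_degenerate:
        logger.info("%d rows with zero variance assigned p = 1", n_degenerate)
    return F, p, ma, mb


def _weighted_anova_two_group(
    a: np.ndarray, b: np.ndarray, wa: np.ndarray, wb: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Coverage-weighted variant: weighted means and sums of squares.

    Weights are read depths; the effective dfs keep the unweighted counts
    so the statistic reduces to the plain ANOVA under equal weights.
    """
    wa = np.where(np.isnan(a), 0.0, wa)
    wb = np.where(np.isnan(b), 0.0, wb)
    a0 = np.where(np.isnan(a), 0.0, a)
    b0 = np.where(np.isnan(b), 0.0, b)
    swa = wa.sum(axis=1)
    swb = wb.sum(axis=1)
    ma = np.where(swa > 0, (wa * a0).sum(axis=1) / np.where(swa > 0, swa, 1), np.nan)
    mb = np.where(swb > 0, (wb * b0).sum(axis=1) / np.where(swb > 0, swb, 1), np.nan)
    na = np.sum(wa > 0, axis=1)
    nb = np.sum(wb > 0, axis=1)
    # normalised weights sum to the group sample count, preserving dfs
    wa_n = wa * (na / np.where(swa > 0, swa, 1))[:, None]
    wb_n = wb * (nb / np.where(swb > 0, swb, 1))[:, None]
    ssa = (wa_n * (a0 - ma[:, None]) ** 2).sum(axis=1)
    ssb = (wb_n * (b0 - mb[:, None]) ** 2).sum(axis=1)
    n = na + nb
    grand = (na * ma + nb * mb) / n
    ss_between = na * (ma - grand) ** 2 + nb * (mb - grand) ** 2
    ss_within = ssa + ssb
    df_within = n - 2.0

    F = np.full(a.shape[0], np.nan)
    p = np.full(a.shape[0], np.nan)
    testable = (na >= 2) & (nb >= 2)
    degenerate = testable & (ss_within <= 0) & (ss_between <= 0)
    ok = testable & ~degenerate
    with np.errstate(divide="ignore", invalid="ignore"):
        F[ok] = ss_between[ok] / (ss_within[ok] / df_within[ok])
    p[ok] = scipy.stats.f.sf(F[ok], 1.0, df_within[ok])
    F[degenerate] = 0.0
    p[degenerate] = 1.0
    return F, p, ma, mb


class DifferentialMethylation:
    """Two-group fragment-level differential-methylation model.

    Parameters
    ----------
    meth : FragmentMethMatrix
        Fragment x sample proportions with coverage mask.
    design : StudyDesign
        Two-group sample assignment; diff = mean(B) - mean(A).
    labels : DataFrame, optional
        Per-fragment ``element_class`` and ``repeat_families`` columns
        (as produced by :func:`conmeth.annotation.classify_fragments`).
    """

    def __init__(
        self,
        meth: FragmentMethMatrix,
        design: StudyDesign,
        labels: pd.DataFrame | None = None,
    ):
        missing = set(design.samples) - set(meth.samples)
        if missing:
            raise ValueError(f"design samples missing from matrix: {sorted(missing)}")
        self.meth = meth
        self.design = design
        self.labels = labels

    def _group_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        ga, gb = self.design.groups
        sa = self.design.samples_of(ga)
        sb = self.design.samples_of(gb)
        vals = self.meth.meth
        mask = self.meth.mask
        a = vals[sa].to_numpy(dtype=float)
        b = vals[sb].to_numpy(dtype=float)
        a = np.where(mask[sa].to_numpy(dtype=bool), a, np.nan)
        b = np.where(mask[sb].to_numpy(dtype=bool), b, np.nan)
        cov_a = self.meth.coverage[sa].to_numpy(dtype=float)
        cov_b = self.meth.coverage[sb].to_numpy(dtype=float)
        return a, b, cov_a, cov_b

    def fit(
        self,
        alpha: float = 0.05,
        delta: float = 0.25,
        coverage_weighted: bool = False,
    ) -> "DMFResults":
        """Call DMFs with an F test at FDR ``alpha`` and minimum absolute
        mean methylation difference ``delta``."""
        a, b, cov_a, cov_b = self._group_arrays()
        if coverage_weighted:
            F, p, ma, mb = _weighted_anova_two_group(a, b, cov_a, cov_b)
        else:
            F, p, ma, mb = _anova_two_group(a, b)

        tested = ~np.isnan(p)
        n_skipped = int((~tested).sum())
        if n_skipped:
            logger.info(
                "%d fragments skipped (fewer than 2 covered samples per group)",
                n_skipped,
            )
        q = np.full_like(p, np.nan)
        if tested.any():
            q[tested] = multipletests(p[tested], method="fdr_bh")[1]

        diff = mb - ma
        table = pd.DataFrame(
            {
                "mean_a": ma,
                "mean_b": mb,
                "diff": diff,
                "F": F,
                "p": p,
                "q": q,
            },
            index=self.meth.meth.index,
        )
        table = table[tested]
        table["is_dmf"] = (table["q"] <= alpha) & (table["diff"].abs() >= delta)
        table["direction"] = np.where(table["diff"] < 0, "hypo", "hyper")
        if self.labels is not None:
            table = table.join(self.labels, how="left")
        return DMFResults(
            table=table,
            alpha=alpha,
            delta=delta,
            design=self.design,
            n_skipped=n_skipped,
            coverage_weighted=coverage_weighted,
        )

    def global_summary(self, paired: bool = False) -> "GlobalSummary":
        """Global and element-wise methylome description.

        Per-sample medians are medians of covered fragment proportions; the
        group comparison is a two-sided rank test between the two
        fragment-wise group-mean vectors (unpaired rank-sum by default, the
        paired signed-rank variant by flag).
        """
        a, b, _, _ = self._group_arrays()
        with np.errstate(invalid="ignore"):
            mean_a = np.nanmean(a, axis=1)
            mean_b = np.nanmean(b, axis=1)
        both = ~np.isnan(mean_a) & ~np.isnan(mean_b)
        if not both.any():
            raise ValueError("no fragment covered in both groups")
        va, vb = mean_a[both], mean_b[both]
        if paired:
            res = scipy.stats.wilcoxon(va, vb, alternative="two-sided")
        else:
            res = scipy.stats.mannwhitneyu(va, vb, alternative="two-sided")
        statistic = float(res.statistic)
        # guard against normal-approximation underflow to exactly 0
        pvalue = max(float(res.pvalue), float(np.nextafter(0, 1)))

        vals = self.meth.meth.where(self.meth.mask)
        per_sample_median = vals.median(axis=0, skipna=True)

        index = self.meth.meth.index[both]
        element_summary = None
        repeat_summary = None
        if self.labels is not None:
            lab = self.labels.reindex(index)
            per_frag = pd.DataFrame(
                {"mean_a": va, "mean_b": vb, "element_class": lab["element_class"]},
                index=index,
            )
            rows = []
            for cls, sub in per_frag.groupby("element_class"):
                rows.append(
                    {
                        "label": cls,
                        "kind": "element",
                        "n_fragments": len(sub),
                        "median_a": sub["mean_a"].median(),
                        "median_b": sub["mean_b"].median(),
                        "median_diff": sub["mean_b"].median() - sub["mean_a"].median(),
                    }
                )
            element_summary = pd.DataFrame(rows).set_index("label")
            fam_rows = []
            fams = lab["repeat_families"].fillna("")
            all_fams = sorted(
                {f for cell in fams for f in str(cell).split(",") if f}
            )
            for fam in all_fams:
                sel = fams.str.split(",").apply(lambda xs: fam in xs)
                sub_a, sub_b = va[sel.to_numpy()], vb[sel.to_numpy()]
                fam_rows.append(
                    {
                        "label": fam,
                        "kind": "repeat",
                        "n_fragments": int(sel.sum()),
                        "median_a": float(np.median(sub_a)),
                        "median_b": float(np.median(sub_b)),
                        "median_diff": float(np.median(sub_b) - np.median(sub_a)),
                    }
                )
            repeat_summary = (
                pd.DataFrame(fam_rows).set_index("label") if fam_rows else None
            )

        return GlobalSummary(
            per_sample_median=per_sample_median,
            group_median={
                self.design.groups[0]: float(np.median(va)),
                self.design.groups[1]: float(np.median(vb)),
            },
            statistic=statistic,
            pvalue=pvalue,
            paired=paired,
            element_summary=element_summary,
            repeat_summary=repeat_summary,
            n_fragments=int(both.sum()),
        )


class GlobalSummary:
    """Descriptive methylome summary for a two-group design."""

    def __init__(
        self,
        per_sample_median: pd.Series,
        group_median: dict[str, float],
        statistic: float,
        pvalue: float,
        paired: bool,
        element_summary: pd.DataFrame | None,
        repeat_summary: pd.DataFrame | None,
        n_fragments: int,
    ):
        for v in group_median.values():
            if not (0.0 <= v <= 1.0):
                raise ValueError("group medians must lie in [0, 1]")
        if not (0.0 < pvalue <= 1.0):
            raise ValueError("p value must lie in (0, 1]")
        self.per_sample_median = per_sample_median
        self.group_median = group_median
        self.statistic = statistic
        self.pvalue = pvalue
        self.paired = paired
        self.element_summary = element_summary
        self.repeat_summary = repeat_summary
        self.n_fragments = n_fragments

    def to_dict(self) -> dict:
        out = {
            "per_sample_median": {k: float(v) for k, v in self.per_sample_median.items()},
            "group_median": self.group_median,
            "rank_test": {
                "statistic": self.statistic,
                "pvalue": self.pvalue,
                "paired": self.paired,
            },
            "n_fragments": self.n_fragments,
        }
        if self.element_summary is not None:
            out["elements"] = self.element_summary.reset_index().to_dict("records")
        if self.repeat_summary is not None:
            out["repeats"] = self.repeat_summary.reset_index().to_dict("records")
        return out


class DMFResults:
    """Results of a DifferentialMethylation fit."""

    def __init__(
        self,
        table: pd.DataFrame,
        alpha: float,
        delta: float,
        design: StudyDesign,
        n_skipped: int,
        coverage_weighted: bool,
    ):
        self.table = table
        self.alpha = alpha
        self.delta = delta
        self.design = design
        self.n_skipped = n_skipped
        self.coverage_weighted = coverage_weighted

    @property
    def dmfs(self) -> pd.DataFrame:
        return self.table[self.table["is_dmf"]]

    @property
    def n_tested(self) -> int:
        return len(self.table)

    @property
    def n_dmf(self) -> int:
        return int(self.table["is_dmf"].sum())

    @property
    def hypo_fraction(self) -> float:
        d = self.dmfs
        if len(d) == 0:
            return float("nan")
        return float((d["direction"] == "hypo").mean())

    def stratify(self, breakpoints: Sequence[float] = (0.25, 0.5, 0.7, 0.75)) -> pd.DataFrame:
        return stratify_dmfs(self.dmfs, breakpoints)

    def summary(self) -> str:
        ga, gb = self.design.groups
        lines = [
            "Differential methylation (two-group F test)",
            "=" * 45,
            f"groups:            {ga} (A, reference) vs {gb} (B)",
            f"fragments tested:  {self.n_tested}",
            f"fragments skipped: {self.n_skipped}",
            f"FDR level alpha:   {self.alpha}",
            f"min |diff| delta:  {self.delta}",
            f"coverage weighted: {self.coverage_weighted}",
            f"DMFs called:       {self.n_dmf}",
        ]
        if self.n_dmf:
            lines.append(f"hypomethylated:    {100 * self.hypo_fraction:.1f}% of DMFs")
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        """BED-compatible table: chrom/start/end first, then the statistics."""
        tab = self.table.copy()
        coords = tab.index.to_series().str.extract(r"(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)")
        tab = pd.concat([coords, tab], axis=1)
        tab.to_csv(path, sep="\t", index_label="fragment")


def global_summary(
    meth: FragmentMethMatrix,
    design: StudyDesign,
    labels: pd.DataFrame | None = None,
    paired: bool = False,
) -> GlobalSummary:
    """Functional wrapper over DifferentialMethylation.global_summary."""
    return DifferentialMethylation(meth, design, labels).global_summary(paired=paired)


def call_dmfs(
    meth: FragmentMethMatrix,
    design: StudyDesign,
    alpha: float = 0.05,
    delta: float = 0.25,
    labels: pd.DataFrame | None = None,
    coverage_weighted: bool = False,
) -> DMFResults:
    """Functional wrapper over DifferentialMethylation.fit."""
    return DifferentialMethylation(meth, design, labels).fit(
        alpha=alpha, delta=delta, coverage_weighted=coverage_weighted
    )


def stratify_dmfs(
    dmfs: pd.DataFrame, breakpoints: Sequence[float] = (0.25, 0.5, 0.7, 0.75)
) -> pd.DataFrame:
    """Count DMFs whose |diff| exceeds each breakpoint, plus the hypo fraction.

    Returns a one-row-per-breakpoint frame with an ``n_above`` column; the
    hypo fraction is attached as ``frame.attrs['hypo_fraction']``.
    """
    if len(dmfs) == 0:
        raise ValueError("no DMFs to stratify")
    absdiff = dmfs["diff"].abs()
    rows = [
        {"breakpoint": bp, "n_above": int((absdiff > bp).sum())} for bp in breakpoints
    ]
    out = pd.DataFrame(rows)
    out.attrs["hypo_fraction"] = float((dmfs["direction"] == "hypo").mean())
    return out


def probe_group_compare(
    beta: pd.DataFrame, design: StudyDesign
) -> pd.DataFrame:
    """Generic two-group comparison of an array-style probe beta matrix.

    Applies the same ANOVA + BH machinery as the fragment test to an
    externally supplied probe x sample matrix of beta values in [0, 1]
    (e.g. a 450K-style panel).  Probes with non-finite values are dropped
    with a logged count.
    """
    missing = set(design.samples) - set(beta.columns)
    if missing:
        raise ValueError(f"design samples missing from matrix: {sorted(missing)}")
    finite = np.isfinite(beta[design.samples].to_numpy(dtype=float)).all(axis=1)
    n_drop = int((~finite).sum())
    if n_drop:
        logger.info("dropped %d probes with non-finite betas", n_drop)
    beta = beta.loc[finite]
    ga, gb = design.groups
    a = beta[design.samples_of(ga)].to_numpy(dtype=float)
    b = beta[design.samples_of(gb)].to_numpy(dtype=float)
    F, p, ma, mb = _anova_two_group(a, b)
    q = np.full_like(p, np.nan)
    tested = ~np.isnan(p)
    if tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]
    return pd.DataFrame(
        {"mean_a": ma, "mean_b": mb, "diff": mb - ma, "F": F, "p": p, "q": q},
        index=beta.index,
    )
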