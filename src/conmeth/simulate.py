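"""Synthetic genomes, methylomes, bisulfite counts and coupled expression.

The generator emulates a 6-vs-6 two-group RRBS + RNA-seq study in which
group B (the constitutive-like group) is globally hypomethylated relative
to group A (the inducible-like group), preferentially at intergenic
fragments, introns and repeat elements, with promoters and exons largely
unchanged.  Expression is coupled to the methylome: planted regulator
genes track the per-sample global methylation level with a chosen rank
correlation, and an anchor gene (*CD274*-like) is higher in the
hypomethylated group.

Noise model: per-CpG read depths are gamma-Poisson (negative binomial)
around a per-fragment, per-sample depth; methylated counts are
beta-binomial with overdispersion phi around the per-sample true
proportion.  Everything is driven by one seed through per-stage child
streams, so stages can be regenerated independently and the whole bundle
is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    GeneRecord,
    GeneTable,
    REPEAT_FAMILIES,
    RepeatAnnotation,
    classify_fragments,
    derive_elements,
)
from .diffmeth import StudyDesign
from .rrbs import (
    Fragment,
    FragmentSet,
    Genome,
    MethCallTable,
    mspi_digest,
    write_meth_calls,
)

logger = logging.getLogger(__name__)

_STAGES = ("genome", "methylome", "counts", "expression", "coupling")

#: class label given to fragments inside the bodies of coupled genes
COUPLED_BODY = "coupled_body"

# default per-class methylation means for the reference group A and the
# group-B deltas; calibrated so the planted global medians sit near the
# 0.63 (A) / 0.47 (B) regime with hypomethylation concentrated in
# intergenic/intron/repeat fragments (promoters stay low, exons unchanged)
DEFAULT_BASELINE = {
    "promoter": 0.10,
    "exon": 0.62,
    "intron": 0.63,
    "intergenic": 0.66,
    "LINE:L1": 0.72,
    "LINE:L2": 0.75,
    "SINE:Alu": 0.70,
    "SINE:MIR": 0.68,
    "LTR:ERV1": 0.70,
    "LTR:ERVK": 0.68,
    "LTR:ERVL": 0.66,
    "LTR:ERVL-MaLR": 0.66,
    "satellite": 0.70,
}
DEFAULT_EFFECT = {
    "promoter": 0.0,
    "exon": 0.0,
    "intron": -0.12,
    "intergenic": -0.19,
    "LINE:L1": -0.19,
    "LINE:L2": -0.11,
    "SINE:Alu": -0.12,
    "SINE:MIR": -0.10,
    "LTR:ERV1": -0.19,
    "LTR:ERVK": -0.16,
    "LTR:ERVL": -0.14,
    "LTR:ERVL-MaLR": -0.13,
    "satellite": -0.12,
}

DEFAULT_REPEAT_DENSITY = {
    "LINE:L1": 0.06,
    "LINE:L2": 0.03,
    "SINE:Alu": 0.08,
    "SINE:MIR": 0.03,
    "LTR:ERV1": 0.03,
    "LTR:ERVK": 0.02,
    "LTR:ERVL": 0.02,
    "LTR:ERVL-MaLR": 0.02,
    "satellite": 0.02,
}

# typical element lengths (bp) per repeat family, jittered at placement
_REPEAT_LENGTH = {
    "LINE:L1": 900,
    "LINE:L2": 500,
    "SINE:Alu": 300,
    "SINE:MIR": 200,
    "LTR:ERV1": 450,
    "LTR:ERVK": 450,
    "LTR:ERVL": 400,
    "LTR:ERVL-MaLR": 350,
    "satellite": 600,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic two-group study.

    Methylation proportions are means in [0, 1]; ``group_effect`` entries
    are group B minus group A deltas.  ``dispersion`` is the beta-binomial
    overdispersion phi in (0, 1); ``coverage_mean``/``coverage_shape``
    parameterise the gamma-Poisson per-CpG read depth.  ``coupling_rho``
    is the target Spearman correlation between the planted regulator gene
    and the per-sample global methylation level (the anchor and the
    opposing regulator get the opposite sign).
    """

    n_chrom: int = 2
    chrom_length: int = 500_000
    cpg_island_rate: float = 10.0  # islands per Mb
    repeat_density: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REPEAT_DENSITY)
    )
    n_per_group: int = 6
    group_names: tuple[str, str] = ("IND", "CON")
    baseline_meth: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE)
    )
    group_effect: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECT))
    frag_noise_sd: float = 0.04  # per-fragment jitter of the class mean
    sample_sd: float = 0.02  # per-sample global offset
    dispersion: float = 0.05
    coverage_mean: float = 30.0  # mean reads per CpG
    coverage_shape: float = 5.0
    size_range: tuple[int, int] = (40, 220)
    n_genes: int = 3000
    n_deg: int = 150
    lfc_scale: float = 3.0
    expr_log2_sd: float = 0.5
    coupling_rho: float = 0.9
    # genes with planted gene-body hypomethylation coupled to
    # down-regulation (the body-hypo/down integration signature)
    n_coupled_genes: int = 8
    coupled_body_delta: float = -0.4
    seed: int = 0

    def validate(self) -> None:
        if self.n_chrom < 1:
            raise ValueError("n_chrom must be >= 1")
        if self.chrom_length < 10_000:
            raise ValueError("chrom_length must be >= 10 kb")
        for fam, frac in self.repeat_density.items():
            if fam not in REPEAT_FAMILIES:
                raise ValueError(f"repeat_density: unknown family {fam!r}")
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"repeat_density[{fam!r}] outside [0, 1]")
        if sum(self.repeat_density.values()) > 0.9:
            raise ValueError("repeat_density fractions must sum to <= 0.9")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for cls, v in self.baseline_meth.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"baseline_meth[{cls!r}] outside [0, 1]")
        for cls, v in self.group_effect.items():
            if not (-1.0 <= v <= 1.0):
                raise ValueError(f"group_effect[{cls!r}] outside [-1, 1]")
        if not (0.0 < self.dispersion < 1.0):
            raise ValueError("dispersion must lie in (0, 1)")
        if self.coverage_mean < 1:
            raise ValueError("coverage_mean must be >= 1")
        if self.coverage_shape <= 0:
            raise ValueError("coverage_shape must be > 0")
        if not (-1.0 <= self.coupling_rho <= 1.0):
            raise ValueError("coupling_rho outside [-1, 1]")
        if self.n_deg > self.n_genes:
            raise ValueError("n_deg must be <= n_genes")

    def rng(self, stage: str) -> np.random.Generator:
        """Per-stage child stream of the one governing seed."""
        if stage not in _STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        root = np.random.SeedSequence(self.seed)
        return np.random.default_rng(root.spawn(len(_STAGES))[_STAGES.index(stage)])

    def design(self) -> StudyDesign:
        ga, gb = self.group_names
        assignment = {}
        for i in range(1, self.n_per_group + 1):
            assignment[f"{ga}_{i}"] = ga
        for i in range(1, self.n_per_group + 1):
            assignment[f"{gb}_{i}"] = gb
        return StudyDesign(assignment, group_order=list(self.group_names))


@dataclass
class SimTruth:
    """Planted ground truth used for parameter-recovery tests."""

    true_frag_meth: pd.DataFrame  # fragment x group true proportions
    sample_meth: pd.DataFrame  # fragment x sample true proportions
    element_of_fragment: pd.Series  # fragment -> one element/repeat class
    sample_global: pd.Series  # per-sample true global (median) methylation
    design: StudyDesign
    true_deg: dict[str, float] = field(default_factory=dict)  # gene -> signed lfc
    true_regulator_rho: dict[str, float] = field(default_factory=dict)
    # genes with planted body hypomethylation + coupled down-regulation
    true_coupled: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.element_of_fragment.isna().any():
            raise ValueError("every fragment needs exactly one element class")

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        frag = self.true_frag_meth.copy()
        frag["element_class"] = self.element_of_fragment
        frag.to_csv(outdir / "truth_fragments.tsv", sep="\t", index_label="fragment")
        self.sample_meth.to_csv(
            outdir / "truth_fragment_samples.tsv", sep="\t", index_label="fragment"
        )
        pd.DataFrame(
            {"gene_id": list(self.true_deg), "true_lfc": list(self.true_deg.values())}
        ).to_csv(outdir / "truth_degs.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "gene_id": list(self.true_regulator_rho),
                "planted_rho": list(self.true_regulator_rho.values()),
            }
        ).to_csv(outdir / "truth_regulators.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))
# CpG-depleted background, as in vertebrate genomes
_BASE_P = np.array([0.30, 0.20, 0.20, 0.30])


def _plant(seq: np.ndarray, pos: int, motif: str) -> None:
    if 0 <= pos and pos + len(motif) <= len(seq):
        seq[pos : pos + len(motif)] = list(motif)


def make_genome(config: SimConfig) -> tuple[Genome, GeneTable, RepeatAnnotation]:
    """Generate a genome with CCGG sites at island and background rates,
    non-overlapping gene models with exon structure, and repeat intervals
    per family at the configured genome fractions."""
    config.validate()
    rng = config.rng("genome")

    genome = Genome()
    genes: list[GeneRecord] = []
    repeat_rows: list[tuple[str, int, int, str]] = []
    gene_counter = 0

    for c in range(config.n_chrom):
        chrom = f"chr{c + 1}"
        L = config.chrom_length
        seq = rng.choice(_BASES, size=L, p=_BASE_P)

        # background MspI sites every ~200 bp on average so digestion
        # yields fragments inside the RRBS size window genome-wide
        pos = 0
        while True:
            pos += int(rng.exponential(200)) + 4
            if pos + 4 >= L:
                break
            _plant(seq, pos, "CCGG")

        # CpG islands: ~800 bp stretches dense in CG and CCGG
        n_islands = rng.poisson(config.cpg_island_rate * L / 1e6)
        for _ in range(n_islands):
            start = int(rng.integers(0, max(1, L - 1000)))
            end = min(L, start + int(rng.integers(600, 1000)))
            p = start
            while p + 4 < end:
                _plant(seq, p, "CCGG" if rng.random() < 0.5 else "CG")
                p += int(rng.integers(20, 70))

        # genes: non-overlapping, with >= ~10 kb gaps leaving room for
        # promoter windows and intergenic fragments
        pos = int(rng.integers(6000, 12000))
        while pos + 18_000 < L:
            glen = int(rng.integers(4000, 12000))
            tx_start, tx_end = pos, pos + glen
            n_exons = int(rng.integers(2, 7))
            # exon boundaries: sorted interior cuts, alternating exon/intron
            cuts = np.sort(rng.choice(np.arange(tx_start + 50, tx_end - 50), size=2 * n_exons - 2, replace=False))
            bounds = [tx_start, *cuts.tolist(), tx_end]
            exon_starts = tuple(bounds[0::2][:n_exons])
            exon_ends = tuple(bounds[1::2][:n_exons])
            strand = "+" if rng.random() < 0.5 else "-"
            gene_counter += 1
            genes.append(
                GeneRecord(
                    f"gene_{gene_counter:05d}",
                    chrom,
                    strand,
                    tx_start,
                    tx_end,
                    exon_starts,
                    exon_ends,
                )
            )
            pos = tx_end + int(rng.integers(10_000, 22_000))

        # CpG-island promoters: a CCGG-dense stretch around each TSS, the
        # reason RRBS enriches for promoters
        for g in genes:
            if g.chrom != chrom:
                continue
            if g.strand == "+":
                lo, hi = g.tss - 4200, g.tss + 800
            else:
                lo, hi = g.tss - 800, g.tss + 4200
            lo, hi = max(0, lo), min(L, hi)
            p = lo
            while p + 4 < hi:
                _plant(seq, p, "CCGG" if rng.random() < 0.75 else "CG")
                p += int(rng.integers(30, 80))

        genome[chrom] = "".join(seq)

        # repeats: per family, place jittered-length intervals avoiding
        # other repeats until the target fraction is covered
        occupied = np.zeros(L, dtype=bool)
        for fam in sorted(config.repeat_density):
            frac = config.repeat_density[fam]
            target = int(frac * L)
            covered = 0
            attempts = 0
            mean_len = _REPEAT_LENGTH[fam]
            while covered < target and attempts < 20 * max(1, target // mean_len):
                attempts += 1
                rlen = max(100, int(rng.normal(mean_len, mean_len / 4)))
                start = int(rng.integers(0, max(1, L - rlen)))
                if occupied[start : start + rlen].any():
                    continue
                occupied[start : start + rlen] = True
                repeat_rows.append((chrom, start, start + rlen, fam))
                covered += rlen

    repeat_frame = pd.DataFrame(
        repeat_rows, columns=["chrom", "start", "end", "family"]
    )
    return genome, GeneTable(genes), RepeatAnnotation(repeat_frame)


# ---------------------------------------------------------------------------
# Methylome
# ---------------------------------------------------------------------------


def make_methylome(
    fragments: FragmentSet,
    labels: Mapping[str, str] | pd.Series,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> SimTruth:
    """Plant true per-group, per-sample methylation proportions.

    Group A proportions are the class baseline plus per-fragment noise;
    group B adds the class effect.  All true proportions are clipped to
    [0.01, 0.99].  Per-sample proportions add a per-sample global offset,
    which is what couples expression to the methylome downstream.
    """
    config.validate()
    if rng is None:
        rng = config.rng("methylome")
    labels = pd.Series(labels)
    names = fragments.names
    missing = [n for n in names if n not in labels.index or pd.isna(labels[n])]
    if missing:
        raise ValueError(f"unlabeled fragments: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    labels = labels[names]
    unknown = set(labels) - set(config.baseline_meth)
    if unknown:
        raise ValueError(f"no baseline_meth entry for classes: {sorted(unknown)}")

    base = labels.map(config.baseline_meth).to_numpy(dtype=float)
    effect = labels.map(lambda c: config.group_effect.get(c, 0.0)).to_numpy(dtype=float)
    noise = rng.normal(0.0, config.frag_noise_sd, size=len(names))
    a = np.clip(base + noise, 0.01, 0.99)
    b = np.clip(a + effect, 0.01, 0.99)

    design = config.design()
    ga, gb = design.groups
    offsets = {s: rng.normal(0.0, config.sample_sd) for s in design.samples}
    sample_cols = {}
    for s in design.samples:
        grp = a if design.group_of(s) == ga else b
        sample_cols[s] = np.clip(grp + offsets[s], 0.01, 0.99)

    true_frag = pd.DataFrame({ga: a, gb: b}, index=names)
    sample_meth = pd.DataFrame(sample_cols, index=names)
    return SimTruth(
        true_frag_meth=true_frag,
        sample_meth=sample_meth,
        element_of_fragment=labels,
        sample_global=sample_meth.median(axis=0),
        design=design,
    )


# ---------------------------------------------------------------------------
# Bisulfite counts
# ---------------------------------------------------------------------------


def sample_counts(
    truth: SimTruth,
    fragments: FragmentSet,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> MethCallTable:
    """Draw per-CpG bisulfite read counts under the beta-binomial model.

    Per fragment and sample, a gamma depth multiplier (mean
    ``coverage_mean``, shape ``coverage_shape``) sets the local coverage;
    per-CpG depths are Poisson around it (a gamma-Poisson, i.e. negative
    binomial, marginal) and methylated counts are beta-binomial with
    overdispersion ``dispersion`` around the per-sample true proportion.
    Zero-depth CpGs produce no record.
    """
    config.validate()
    if rng is None:
        rng = config.rng("counts")
    phi = config.dispersion

    samples = truth.design.samples
    names = fragments.names
    n_cpg = np.array([len(p) for p in fragments.cpg_positions])
    if (n_cpg == 0).any():
        keep = n_cpg > 0
        logger.info("skipping %d CpG-free fragments", int((~keep).sum()))
    frag_idx = np.repeat(np.arange(len(names)), n_cpg)
    all_pos = (
        np.concatenate([p for p in fragments.cpg_positions])
        if len(frag_idx)
        else np.empty(0, dtype=np.int64)
    )
    all_chrom = np.array([fragments[i].chrom for i in frag_idx]) if len(frag_idx) else np.empty(0, dtype=object)

    S = len(samples)
    C = len(frag_idx)
    lam = rng.gamma(
        config.coverage_shape,
        config.coverage_mean / config.coverage_shape,
        size=(len(names), S),
    )
    depth = rng.poisson(lam[frag_idx, :], size=(C, S))
    p_true = truth.sample_meth.loc[names].to_numpy(dtype=float)[frag_idx, :]
    if phi < 1e-8:
        p_cpg = p_true
    else:
        alpha = p_true * (1.0 - phi) / phi
        beta = (1.0 - p_true) * (1.0 - phi) / phi
        p_cpg = rng.beta(np.maximum(alpha, 1e-12), np.maximum(beta, 1e-12))
    n_meth = rng.binomial(depth, p_cpg)

    rows = np.nonzero(depth > 0)
    frame = pd.DataFrame(
        {
            "chrom": all_chrom[rows[0]],
            "pos": all_pos[rows[0]],
            "sample_id": np.array(samples, dtype=object)[rows[1]],
            "n_meth": n_meth[rows],
            "n_unmeth": depth[rows] - n_meth[rows],
        }
    )
    return MethCallTable(frame)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

ANCHOR_GENE = "CD274"
REGULATOR_POS = "DNMT3A"  # planted +coupling_rho vs global methylation
REGULATOR_NEG = "UHRF2"  # planted -coupling_rho vs global methylation


def make_expression(
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    gene_ids: Sequence[str] | None = None,
    forced_deg: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Generate a log-normal FPKM matrix coupled to the planted methylome.

    ``n_deg`` genes receive group-B shifts of +-``lfc_scale`` log2 units.
    The planted regulators track the standardised per-sample global
    methylation with rank coupling ``coupling_rho`` (DNMT3A-like positive,
    UHRF2-like negative); the anchor gene couples negatively, making it
    higher in the hypomethylated group.  Returns the matrix and the truth
    updated with planted DEG effects and regulator correlations.
    """
    config.validate()
    if rng is None:
        rng = config.rng("expression")
    design = truth.design
    samples = design.samples
    ga, gb = design.groups
    is_b = np.array([design.group_of(s) == gb for s in samples])

    special = [ANCHOR_GENE, REGULATOR_POS, REGULATOR_NEG]
    n_plain = config.n_genes - len(special)
    if n_plain < 0:
        raise ValueError("n_genes must cover the anchor and regulator genes")
    # plain genes take supplied ids first (e.g. the genome's gene models,
    # so expression joins onto genomic coordinates), then filler ids
    supplied = list(gene_ids)[:n_plain] if gene_ids is not None else []
    gene_ids = special + supplied + [
        f"expr_{i + 1:05d}" for i in range(n_plain - len(supplied))
    ]

    g = truth.sample_global[samples].to_numpy(dtype=float)
    sd = g.std(ddof=0)
    z = (g - g.mean()) / sd if sd > 0 else np.zeros_like(g)

    mu = rng.normal(3.0, 1.5, size=config.n_genes)
    x = mu[:, None] + rng.normal(0.0, config.expr_log2_sd, size=(config.n_genes, len(samples)))

    # planted DEGs among the plain genes; their baselines are drawn from
    # the expressed range, since the pseudocount floors the measurable
    # fold change of near-silent genes (a property of FPKM fold changes,
    # not of the test)
    if config.n_deg > n_plain:
        raise ValueError("n_deg exceeds the number of non-anchor genes")
    deg_rows = rng.choice(np.arange(len(special), config.n_genes), size=config.n_deg, replace=False)
    signs = rng.choice([-1.0, 1.0], size=config.n_deg)
    mu[deg_rows] = rng.normal(4.5, 1.0, size=config.n_deg)
    x[deg_rows, :] = mu[deg_rows, None] + rng.normal(
        0.0, config.expr_log2_sd, size=(config.n_deg, len(samples))
    )
    for row, s in zip(deg_rows, signs):
        x[row, is_b] += s * config.lfc_scale

    # forced effects (e.g. body-methylation-coupled genes): fixed signed
    # shifts on named genes, planted like ordinary DEGs
    true_deg = {gene_ids[r]: float(s * config.lfc_scale) for r, s in zip(deg_rows, signs)}
    if forced_deg:
        index_of = {g: i for i, g in enumerate(gene_ids)}
        for gene, shift in forced_deg.items():
            if gene not in index_of:
                raise ValueError(f"forced DEG {gene!r} not among gene ids")
            row = index_of[gene]
            mu[row] = rng.normal(4.5, 1.0)
            x[row, :] = mu[row] + rng.normal(0.0, config.expr_log2_sd, size=len(samples))
            x[row, is_b] += shift
            true_deg[gene] = float(shift)

    # methylome-coupled genes: Gaussian copula on the standardised
    # per-sample global methylation
    rho = config.coupling_rho
    resid = np.sqrt(max(0.0, 1.0 - rho**2))
    coupling_sd = 1.5  # log2 spread of the coupled signal
    for row, sign in ((0, -1.0), (1, +1.0), (2, -1.0)):
        eps = rng.normal(0.0, 1.0, size=len(samples))
        x[row] = mu[row] + coupling_sd * (sign * rho * z + resid * eps)

    expr = pd.DataFrame(np.power(2.0, x), index=gene_ids, columns=samples)
    truth = dataclasses.replace(
        truth,
        true_deg=true_deg,
        true_regulator_rho={
            ANCHOR_GENE: -rho,
            REGULATOR_POS: +rho,
            REGULATOR_NEG: -rho,
        },
    )
    return expr, truth


# ---------------------------------------------------------------------------
# Convenience constructions
# ---------------------------------------------------------------------------


def synthetic_fragment_set(
    n_fragments: int, n_cpg: int = 4, length: int = 100, chrom: str = "sim"
) -> FragmentSet:
    """Abstract fragments (no genome) for direct statistical simulations."""
    fragments = []
    cpgs = []
    for i in range(n_fragments):
        start = i * length
        fragments.append(Fragment(chrom, start, start + length, n_cpg))
        cpgs.append(start + 2 + np.arange(n_cpg, dtype=np.int64) * (length // (n_cpg + 1)))
    return FragmentSet(fragments, cpgs)


def assign_classes(
    fragments: FragmentSet,
    elements,
    repeats: RepeatAnnotation,
    min_repeat_overlap: float = 0.5,
) -> tuple[pd.Series, pd.DataFrame]:
    """Map each fragment to the single class used for methylome planting.

    A fragment majority-covered by a repeat gets that family as its class
    (largest-coverage family on ties); otherwise its element class.
    Returns (class series, full classification table).
    """
    table = classify_fragments(fragments, elements, repeats, min_repeat_overlap)
    cls = []
    for name, row in table.iterrows():
        fams = [f for f in str(row["repeat_families"]).split(",") if f]
        cls.append(sorted(fams)[0] if fams else row["element_class"])
    return pd.Series(cls, index=table.index), table


@dataclass
class SimBundle:
    """All artefacts of one synthetic study."""

    genome: Genome
    genes: GeneTable
    repeats: RepeatAnnotation
    fragments: FragmentSet
    labels: pd.Series
    classification: pd.DataFrame
    truth: SimTruth
    calls: MethCallTable
    expression: pd.DataFrame
    design: StudyDesign


def _pick_coupled_genes(
    fragments: FragmentSet,
    genes: GeneTable,
    labels: pd.Series,
    config: SimConfig,
) -> tuple[pd.Series, list[str]]:
    """Relabel body fragments of a few genes as the coupled-body class.

    These genes model the body-hypo/down-regulation signature: their
    gene-body fragments receive a strong methylation loss and their
    expression a matching down-shift.
    """
    if config.n_coupled_genes == 0:
        return labels, []
    rng = config.rng("coupling")
    frag_frame = pd.DataFrame(
        {"chrom": [f.chrom for f in fragments],
         "start": [f.start for f in fragments],
         "end": [f.end for f in fragments]},
        index=fragments.names,
    )
    candidates: dict[str, list[str]] = {}
    for g in genes:
        p_lo, p_hi = g.promoter(None)
        sel = frag_frame[
            (frag_frame["chrom"] == g.chrom)
            & (frag_frame["start"] >= g.tx_start)
            & (frag_frame["end"] <= g.tx_end)
            # outside the promoter window, i.e. genuinely gene body
            & ((frag_frame["end"] <= p_lo) | (frag_frame["start"] >= p_hi))
        ]
        if len(sel) >= 2:
            candidates[g.gene_id] = list(sel.index)
    if not candidates:
        return labels, []
    chosen = list(
        rng.choice(sorted(candidates), size=min(config.n_coupled_genes, len(candidates)),
                   replace=False)
    )
    labels = labels.copy()
    for gene_id in chosen:
        labels.loc[candidates[gene_id]] = COUPLED_BODY
    return labels, chosen


def simulate_bundle(config: SimConfig | None = None) -> SimBundle:
    """Run every generator stage under one seed and return the bundle."""
    if config is None:
        config = SimConfig()
    config.validate()
    genome, genes, repeats = make_genome(config)
    fragments = mspi_digest(genome, size_range=config.size_range)
    elements = derive_elements(genes, genome.lengths)
    labels, classification = assign_classes(fragments, elements, repeats)
    labels, coupled = _pick_coupled_genes(fragments, genes, labels, config)
    cfg = config
    if coupled:
        cfg = dataclasses.replace(
            config,
            baseline_meth={**config.baseline_meth, COUPLED_BODY: 0.65},
            group_effect={**config.group_effect, COUPLED_BODY: config.coupled_body_delta},
        )
    truth = make_methylome(fragments, labels, cfg)
    calls = sample_counts(truth, fragments, cfg)
    expression, truth = make_expression(
        truth,
        cfg,
        gene_ids=[g.gene_id for g in genes],
        forced_deg={g: -cfg.lfc_scale for g in coupled},
    )
    truth = dataclasses.replace(
        truth, true_coupled={g: cfg.coupled_body_delta for g in coupled}
    )
    return SimBundle(
        genome=genome,
        genes=genes,
        repeats=repeats,
        fragments=fragments,
        labels=labels,
        classification=classification,
        truth=truth,
        calls=calls,
        expression=expression,
        design=truth.design,
    )


def write_bundle(bundle: SimBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the synthetic study to disk in the pipeline's input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    bundle.genome.to_fasta(outdir / "genome.fa")
    paths["genome"] = outdir / "genome.fa"
    bundle.genes.to_tsv(outdir / "genes.tsv")
    paths["genes"] = outdir / "genes.tsv"
    bundle.repeats.to_bed(outdir / "repeats.bed")
    paths["repeats"] = outdir / "repeats.bed"
    bundle.design.to_tsv(outdir / "design.tsv")
    paths["design"] = outdir / "design.tsv"
    cov_dir = outdir / "coverage"
    write_meth_calls(bundle.calls, cov_dir)
    paths["coverage_dir"] = cov_dir
    bundle.expression.to_csv(outdir / "expression.tsv", sep="\t", index_label="gene_id")
    paths["expression"] = outdir / "expression.tsv"
    bundle.truth.write(outdir)
    paths["truth"] = outdir / "truth_fragments.tsv"
    return paths
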