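"""Genomic-element derivation and fragment classification.

Elements are the four classes used for methylome stratification:
promoter (TSS -5 kb to +1 kb in transcription orientation), exon, intron,
and intergenic.  Repeat families follow the RepeatMasker vocabulary used
for repeat-wise methylation profiles (LINE L1/L2, SINE Alu/MIR, LTR ERV
subfamilies, satellite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .rrbs import Fragment, FragmentSet

logger = logging.getLogger(__name__)

ELEMENT_CLASSES = ("promoter", "exon", "intron", "intergenic")
#: classification precedence for fragments overlapping several classes
ELEMENT_PRECEDENCE = ("promoter", "exon", "intron")

REPEAT_FAMILIES = (
    "LINE:L1",
    "LINE:L2",
    "SINE:Alu",
    "SINE:MIR",
    "LTR:ERV1",
    "LTR:ERVK",
    "LTR:ERVL",
    "LTR:ERVL-MaLR",
    "satellite",
)

PROMOTER_UPSTREAM = 5000
PROMOTER_DOWNSTREAM = 1000


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if self.tx_start >= self.tx_end:
            raise ValueError(f"gene {self.gene_id}: empty transcript span")
        if len(self.exon_starts) != len(self.exon_ends):
            raise ValueError(f"gene {self.gene_id}: ragged exon lists")
        prev_end = None
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"gene {self.gene_id}: exon [{s},{e}) outside span")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    def promoter(
        self,
        chrom_length: int | None = None,
        upstream: int = PROMOTER_UPSTREAM,
        downstream: int = PROMOTER_DOWNSTREAM,
    ) -> tuple[int, int]:
        """Promoter window in transcription orientation, clipped to the chromosome."""
        if self.strand == "+":
            lo, hi = self.tss - upstream, self.tss + downstream
        else:
            lo, hi = self.tss - downstream, self.tss + upstream
        lo = max(lo, 0)
        if chrom_length is not None:
            hi = min(hi, chrom_length)
        return lo, hi


class GeneTable:
    """Gene models: transcript span, strand and exon structure per gene."""

    def __init__(self, genes: Sequence[GeneRecord]):
        ids = [g.gene_id for g in genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids")
        self.genes = list(genes)
        self._by_id = {g.gene_id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneTable":
        """Schema: gene_id chrom strand tx_start tx_end exon_starts exon_ends
        (exon lists comma-separated; 0-based half-open)."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        genes = []
        for row in df.itertuples(index=False):
            genes.append(
                GeneRecord(
                    gene_id=row.gene_id,
                    chrom=row.chrom,
                    strand=row.strand,
                    tx_start=int(row.tx_start),
                    tx_end=int(row.tx_end),
                    exon_starts=tuple(
                        int(x) for x in str(row.exon_starts).rstrip(",").split(",") if x
                    ),
                    exon_ends=tuple(
                        int(x) for x in str(row.exon_ends).rstrip(",").split(",") if x
                    ),
                )
            )
        return cls(genes)

    @classmethod
    def from_bed12(cls, path: str | Path) -> "GeneTable":
        genes = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                chrom, start, end, name, _score, strand = f[:6]
                start, end = int(start), int(end)
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                exon_starts = tuple(start + o for o in offsets)
                exon_ends = tuple(s + sz for s, sz in zip(exon_starts, sizes))
                genes.append(
                    GeneRecord(name, chrom, strand, start, end, exon_starts, exon_ends)
                )
        return cls(genes)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "tx_start": g.tx_start,
                "tx_end": g.tx_end,
                "exon_starts": ",".join(map(str, g.exon_starts)),
                "exon_ends": ",".join(map(str, g.exon_ends)),
            }
            for g in self.genes
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


class RepeatAnnotation:
    """RepeatMasker-style repeat intervals with family labels."""

    def __init__(self, frame: pd.DataFrame, vocabulary: Iterable[str] = REPEAT_FAMILIES):
        required = {"chrom", "start", "end", "family"}
        if not required.issubset(frame.columns):
            raise ValueError(f"repeat annotation needs columns {sorted(required)}")
        vocab = set(vocabulary)
        bad = set(frame["family"]) - vocab
        if bad:
            raise ValueError(f"unknown repeat families: {sorted(bad)}")
        if (frame["start"] >= frame["end"]).any():
            raise ValueError("invalid repeat intervals")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_bed(cls, path: str | Path) -> "RepeatAnnotation":
        """BED with the family label in column 4 (name)."""
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                rows.append((f[0], int(f[1]), int(f[2]), f[3]))
        frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "family"])
        return cls(frame)

    @classmethod
    def empty(cls) -> "RepeatAnnotation":
        return cls(pd.DataFrame(columns=["chrom", "start", "end", "family"]))

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for row in self.frame.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.family}\t0\t.\n")


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if s >= e:
            continue
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _complement(ivs: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    out = []
    prev = 0
    for s, e in ivs:
        if s > prev:
            out.append((prev, s))
        prev = max(prev, e)
    if prev < length:
        out.append((prev, length))
    return out


class ElementMap:
    """Per-class interval sets (merged, 0-based half-open) for one genome."""

    def __init__(self, intervals: Mapping[str, Mapping[str, list[tuple[int, int]]]]):
        # intervals[class][chrom] -> merged interval list
        self.intervals = {
            cls: {c: _merge_intervals(list(ivs)) for c, ivs in per.items()}
            for cls, per in intervals.items()
        }
        self._trees: dict[tuple[str, str], IntervalTree] = {}

    def tree(self, cls: str, chrom: str) -> IntervalTree:
        key = (cls, chrom)
        if key not in self._trees:
            ivs = self.intervals.get(cls, {}).get(chrom, [])
            self._trees[key] = IntervalTree.from_tuples((s, e) for s, e in ivs)
        return self._trees[key]

    def overlap_bp(self, cls: str, fragment: Fragment) -> int:
        total = 0
        for iv in self.tree(cls, fragment.chrom).overlap(fragment.start, fragment.end):
            total += min(iv.end, fragment.end) - max(iv.begin, fragment.start)
        return total

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for cls in ELEMENT_CLASSES:
                for chrom, ivs in sorted(self.intervals.get(cls, {}).items()):
                    for s, e in ivs:
                        fh.write(f"{chrom}\t{s}\t{e}\t{cls}\t0\t.\n")


def derive_elements(
    genes: GeneTable,
    genome_lengths: Mapping[str, int],
    promoter_upstream: int = PROMOTER_UPSTREAM,
    promoter_downstream: int = PROMOTER_DOWNSTREAM,
) -> ElementMap:
    """Compute promoter / exon / intron / intergenic interval sets.

    Promoters run from ``upstream`` bp before the TSS to ``downstream`` bp
    after it, in transcription orientation (reflected for minus-strand
    genes), clipped to the chromosome.  Introns are gene spans minus exons;
    intergenic is the complement of gene spans and promoters.  Promoter
    windows are carved out of exons and introns so a TSS-proximal exonic
    base counts as promoter.
    """
    promoters: dict[str, list[tuple[int, int]]] = {c: [] for c in genome_lengths}
    exons: dict[str, list[tuple[int, int]]] = {c: [] for c in genome_lengths}
    introns: dict[str, list[tuple[int, int]]] = {c: [] for c in genome_lengths}
    gene_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in genome_lengths}

    for g in genes:
        length = genome_lengths.get(g.chrom)
        if length is None:
            raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
        if g.tx_end > length:
            raise ValueError(f"gene {g.gene_id}: exceeds chromosome bounds")
        promoters[g.chrom].append(
            g.promoter(length, promoter_upstream, promoter_downstream)
        )
        gene_spans[g.chrom].append((g.tx_start, g.tx_end))
        ex = list(zip(g.exon_starts, g.exon_ends))
        exons[g.chrom].extend(ex)
        # introns: transcript span minus exon union
        for s, e in _complement(_merge_intervals(ex), g.tx_end):
            s = max(s, g.tx_start)
            if s < e:
                introns[g.chrom].append((s, e))

    # carve promoters out of exons/introns; intergenic = complement of
    # (gene spans union promoters)
    result: dict[str, dict[str, list[tuple[int, int]]]] = {
        "promoter": {},
        "exon": {},
        "intron": {},
        "intergenic": {},
    }
    for chrom, length in genome_lengths.items():
        prom = _merge_intervals(promoters[chrom])
        result["promoter"][chrom] = prom
        result["exon"][chrom] = _subtract(_merge_intervals(exons[chrom]), prom)
        result["intron"][chrom] = _subtract(_merge_intervals(introns[chrom]), prom)
        covered = _merge_intervals(gene_spans[chrom] + prom)
        result["intergenic"][chrom] = _complement(covered, length)
    return ElementMap(result)


def _subtract(
    ivs: list[tuple[int, int]], minus: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Set difference of merged interval lists."""
    out = []
    j = 0
    for s, e in ivs:
        cur = s
        while j < len(minus) and minus[j][1] <= cur:
            j += 1
        k = j
        while k < len(minus) and minus[k][0] < e:
            ms, me = minus[k]
            if ms > cur:
                out.append((cur, ms))
            cur = max(cur, me)
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


class _RepeatIndex:
    def __init__(self, repeats: RepeatAnnotation):
        self.trees: dict[str, IntervalTree] = {}
        for row in repeats.frame.itertuples(index=False):
            self.trees.setdefault(row.chrom, IntervalTree()).addi(
                int(row.start), int(row.end), row.family
            )


def classify_fragment(
    fragment: Fragment,
    elements: ElementMap,
    repeats: RepeatAnnotation | _RepeatIndex | None = None,
    min_repeat_overlap: float = 0.5,
) -> tuple[str, frozenset[str]]:
    """Assign an element class and the covering repeat families to a fragment.

    The element class is the first of promoter > exon > intron with at
    least 1 bp of overlap, else intergenic.  Repeat families are all
    families whose intervals cover at least ``min_repeat_overlap`` of the
    fragment length (independent of the element class).
    """
    cls = "intergenic"
    for candidate in ELEMENT_PRECEDENCE:
        if elements.overlap_bp(candidate, fragment) > 0:
            cls = candidate
            break

    families: set[str] = set()
    if repeats is not None:
        index = repeats if isinstance(repeats, _RepeatIndex) else _RepeatIndex(repeats)
        tree = index.trees.get(fragment.chrom)
        if tree is not None:
            per_family: dict[str, list[tuple[int, int]]] = {}
            for iv in tree.overlap(fragment.start, fragment.end):
                per_family.setdefault(iv.data, []).append(
                    (max(iv.begin, fragment.start), min(iv.end, fragment.end))
                )
            for family, ivs in per_family.items():
                covered = sum(e - s for s, e in _merge_intervals(ivs))
                if covered >= min_repeat_overlap * fragment.length:
                    families.add(family)
    return cls, frozenset(families)


def classify_fragments(
    fragments: FragmentSet,
    elements: ElementMap,
    repeats: RepeatAnnotation | None = None,
    min_repeat_overlap: float = 0.5,
) -> pd.DataFrame:
    """Vector form of :func:`classify_fragment`; one row per fragment."""
    index = _RepeatIndex(repeats) if repeats is not None else None
    rows = []
    for f in fragments:
        cls, fams = classify_fragment(f, elements, index, min_repeat_overlap)
        rows.append({"element_class": cls, "repeat_families": ",".join(sorted(fams))})
    return pd.DataFrame(rows, index=fragments.names)
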