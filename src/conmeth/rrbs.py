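"""In-silico MspI digestion and fragment-level methylation quantification.

Reduced representation bisulfite sequencing (RRBS) enriches for CpG-dense
genomic regions by digesting the genome with MspI (recognition site C^CGG)
and size-selecting the resulting fragments.  The MspI fragment is therefore
the natural unit of methylation quantification: per-CpG read counts are
pooled over the CpGs of a fragment, and a fragment-by-sample matrix of
methylation proportions is the input to all downstream statistics.

All internal coordinates are 0-based, half-open.  Only the Bismark
coverage dialect (1-based, inclusive) converts at the file boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pyfaidx

logger = logging.getLogger(__name__)

# MspI recognition site; the enzyme cuts between the first C and the CGG.
_MSPI_SITE = "CCGG"
_MSPI_CUT_OFFSET = 1

# lookahead so that overlapping occurrences are all reported
_MSPI_RE = re.compile(r"(?=CCGG)")
_CPG_RE = re.compile(r"(?=CG)")


class Genome(dict):
    """Chromosome name -> uppercase sequence (A/C/G/T/N).

    A thin dict subclass so that sequences read from FASTA and sequences
    built in memory share one type.
    """

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        genome = cls({name: str(fa[name][:]) for name in fa.keys()})
        fa.close()
        genome.validate()
        return genome

    def validate(self) -> None:
        for name, seq in self.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} has an empty sequence")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.items()}

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class Fragment:
    """An MspI fragment: the interval between two consecutive cut positions."""

    chrom: str
    start: int  # 0-based
    end: int  # half-open
    n_cpg: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"fragment {self.chrom}:{self.start}-{self.end} is empty")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


class FragmentSet:
    """Ordered collection of disjoint fragments with per-fragment CpG positions.

    CpG positions (the C of each CG dinucleotide, 0-based) are recorded at
    digestion time so that downstream simulation and quantification never
    need the sequence again.
    """

    def __init__(
        self,
        fragments: Sequence[Fragment],
        cpg_positions: Sequence[np.ndarray] | None = None,
    ):
        self.fragments = list(fragments)
        if cpg_positions is None:
            cpg_positions = [np.empty(0, dtype=np.int64) for _ in self.fragments]
        if len(cpg_positions) != len(self.fragments):
            raise ValueError("cpg_positions must parallel fragments")
        self.cpg_positions = [np.asarray(p, dtype=np.int64) for p in cpg_positions]

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self) -> Iterator[Fragment]:
        return iter(self.fragments)

    def __getitem__(self, i: int) -> Fragment:
        return self.fragments[i]

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.fragments]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [f.chrom for f in self.fragments],
                "start": [f.start for f in self.fragments],
                "end": [f.end for f in self.fragments],
                "n_cpg": [f.n_cpg for f in self.fragments],
            },
            index=self.names,
        )

    def to_bed(self, path: str | Path) -> None:
        """BED6 with score = CpG count."""
        with open(path, "w") as fh:
            for f in self.fragments:
                fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.name}\t{f.n_cpg}\t.\n")


def _cut_positions(seq: str) -> list[int]:
    return [m.start() + _MSPI_CUT_OFFSET for m in _MSPI_RE.finditer(seq)]


def _cpg_positions(seq: str, offset: int = 0) -> np.ndarray:
    return np.array([m.start() + offset for m in _CPG_RE.finditer(seq)], dtype=np.int64)


def mspi_digest(
    genome: Mapping[str, str],
    size_range: tuple[int, int] | None = None,
) -> FragmentSet:
    """Digest a genome at every MspI site and optionally size-select.

    Cuts fall between the first C and the CGG of each CCGG occurrence
    (offset +1 from the match start); fragments are the intervals between
    consecutive cuts, closed by the chromosome ends.  Before size selection
    the fragments of a chromosome tile it exactly.  N-containing sites
    never match.

    Parameters
    ----------
    genome : mapping of chromosome name to uppercase sequence
    size_range : (min_bp, max_bp) inclusive window, or None for no selection
    """
    if not genome:
        raise ValueError("genome is empty")
    if size_range is not None:
        min_bp, max_bp = size_range
        if min_bp > max_bp:
            raise ValueError(f"size_range min {min_bp} > max {max_bp}")

    fragments: list[Fragment] = []
    cpgs: list[np.ndarray] = []
    for chrom in genome:
        seq = genome[chrom]
        bounds = [0] + _cut_positions(seq) + [len(seq)]
        for start, end in zip(bounds[:-1], bounds[1:]):
            if start == end:  # cut at position 0 would create an empty piece
                continue
            if size_range is not None and not (min_bp <= end - start <= max_bp):
                continue
            sub = seq[start:end]
            pos = _cpg_positions(sub, offset=start)
            fragments.append(Fragment(chrom, start, end, len(pos)))
            cpgs.append(pos)
    return FragmentSet(fragments, cpgs)


# ---------------------------------------------------------------------------
# CpG methylation calls
# ---------------------------------------------------------------------------


class MethCallTable:
    """Per-CpG, per-sample methylated/unmethylated read counts.

    Backed by a DataFrame with columns (chrom, pos, sample_id, n_meth,
    n_unmeth); pos is the 0-based position of the CpG cytosine.
    """

    COLUMNS = ["chrom", "pos", "sample_id", "n_meth", "n_unmeth"]

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"MethCallTable missing columns: {sorted(missing)}")
        if (frame["n_meth"] < 0).any() or (frame["n_unmeth"] < 0).any():
            raise ValueError("negative read counts")
        if frame.duplicated(["chrom", "pos", "sample_id"]).any():
            raise ValueError("duplicate (chrom, pos, sample) records")
        self.frame = frame[self.COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def samples(self) -> list[str]:
        return sorted(self.frame["sample_id"].unique())


def load_meth_calls(
    paths: Mapping[str, str | Path] | str | Path,
    dialect: str = "bismark_cov",
    sample_id: str | None = None,
) -> MethCallTable:
    """Read CpG methylation calls in Bismark coverage format.

    The Bismark coverage dialect is 1-based inclusive:
    ``chrom  start  end  %methylation  count_methylated  count_unmethylated``.
    Positions are converted to 0-based on load.  Rows with zero total reads
    are dropped (count logged); a percentage inconsistent with the counts by
    more than 0.5 points is rejected.

    Parameters
    ----------
    paths : one path (requires ``sample_id``) or a mapping sample_id -> path
    """
    if dialect != "bismark_cov":
        raise ValueError(f"unknown dialect {dialect!r}")
    if not isinstance(paths, Mapping):
        if sample_id is None:
            raise ValueError("sample_id required when loading a single file")
        paths = {sample_id: paths}

    records = []
    n_zero = 0
    for sid, path in paths.items():
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                fields = line.split("\t") if "\t" in line else line.split()
                if len(fields) != 6:
                    raise ValueError(
                        f"{path}:{lineno}: expected 6 fields, got {len(fields)}"
                    )
                chrom, start_s, _end_s, pct_s, meth_s, unmeth_s = fields
                try:
                    start = int(start_s)
                    pct = float(pct_s)
                    n_meth = int(meth_s)
                    n_unmeth = int(unmeth_s)
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed line: {exc}") from exc
                if start < 1:
                    raise ValueError(
                        f"{path}:{lineno}: 1-based coordinate {start} out of range"
                    )
                total = n_meth + n_unmeth
                if total == 0:
                    n_zero += 1
                    continue
                if abs(pct - 100.0 * n_meth / total) > 0.5:
                    raise ValueError(
                        f"{path}:{lineno}: percentage {pct} inconsistent with "
                        f"counts {n_meth}/{n_unmeth}"
                    )
                records.append((chrom, start - 1, sid, n_meth, n_unmeth))
    if n_zero:
        logger.info("dropped %d zero-coverage records", n_zero)
    frame = pd.DataFrame(records, columns=MethCallTable.COLUMNS)
    return MethCallTable(frame)


def write_meth_calls(calls: MethCallTable, outdir: str | Path) -> dict[str, Path]:
    """Write one Bismark coverage file per sample (1-based inclusive)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sid, sub in calls.frame.groupby("sample_id", sort=True):
        path = outdir / f"{sid}.cov"
        sub = sub.sort_values(["chrom", "pos"])
        with open(path, "w") as fh:
            for row in sub.itertuples(index=False):
                total = row.n_meth + row.n_unmeth
                pct = 100.0 * row.n_meth / total
                fh.write(
                    f"{row.chrom}\t{row.pos + 1}\t{row.pos + 1}\t"
                    f"{pct:.6g}\t{row.n_meth}\t{row.n_unmeth}\n"
                )
        paths[str(sid)] = path
    return paths


# ---------------------------------------------------------------------------
# Fragment quantification
# ---------------------------------------------------------------------------


class FragmentMethMatrix:
    """Fragment x sample methylation proportions with coverage and mask.

    ``meth`` holds the pooled proportion sum(n_meth)/sum(n_meth+n_unmeth)
    over the CpGs of the fragment (NaN where the cell is not covered);
    ``coverage`` the total informing reads; ``mask`` whether the cell meets
    the coverage threshold.
    """

    def __init__(
        self,
        meth: pd.DataFrame,
        coverage: pd.DataFrame,
        mask: pd.DataFrame,
        fragments: FragmentSet | None = None,
    ):
        if not (meth.shape == coverage.shape == mask.shape):
            raise ValueError("meth, coverage and mask must share a shape")
        vals = meth.to_numpy(dtype=float)
        ok = mask.to_numpy(dtype=bool)
        inside = vals[ok]
        if inside.size and (np.nanmin(inside) < 0 or np.nanmax(inside) > 1):
            raise ValueError("methylation proportions outside [0, 1]")
        self.meth = meth
        self.coverage = coverage
        self.mask = mask
        self.fragments = fragments

    @property
    def shape(self) -> tuple[int, int]:
        return self.meth.shape

    @property
    def samples(self) -> list[str]:
        return list(self.meth.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.meth.to_csv(path, sep="\t", index_label="fragment")


def quantify_fragments(
    calls: MethCallTable,
    fragments: FragmentSet,
    min_reads: int = 10,
    min_samples_per_group: int = 3,
    design: "StudyDesign | None" = None,
) -> FragmentMethMatrix:
    """Pool per-CpG counts into per-fragment methylation proportions.

    A fragment-sample cell is *covered* iff the summed reads over the
    fragment's CpGs reach ``min_reads``.  A fragment is retained iff it is
    covered in at least ``min_samples_per_group`` samples in each group of
    the design (coverage standardisation).  Fragments without CpGs are
    excluded up front (count logged).  Proportions are pooled, i.e.
    read-weighted over CpGs, not means of per-CpG proportions.
    """
    from .diffmeth import StudyDesign  # local import to avoid a cycle

    if design is not None:
        known = set(design.samples)
        extra = set(calls.frame["sample_id"].unique()) - known
        if extra:
            raise ValueError(f"samples absent from design: {sorted(extra)}")

    keep_idx = [i for i, f in enumerate(fragments) if f.n_cpg > 0]
    n_nocpg = len(fragments) - len(keep_idx)
    if n_nocpg:
        logger.info("excluded %d fragments without CpGs", n_nocpg)

    samples = calls.samples
    frame = calls.frame

    # assign each call to a fragment by binary search over disjoint intervals
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i in keep_idx:
        f = fragments[i]
        by_chrom.setdefault(f.chrom, []).append((f.start, f.end, i))
    for chrom in by_chrom:
        by_chrom[chrom].sort()

    n_frag = len(keep_idx)
    frag_order = {i: j for j, i in enumerate(keep_idx)}
    s_order = {s: j for j, s in enumerate(samples)}
    meth_mat = np.zeros((n_frag, len(samples)), dtype=np.int64)
    total_mat = np.zeros((n_frag, len(samples)), dtype=np.int64)

    for chrom, sub in frame.groupby("chrom", sort=False):
        intervals = by_chrom.get(chrom)
        if not intervals:
            continue
        starts = np.array([iv[0] for iv in intervals])
        ends = np.array([iv[1] for iv in intervals])
        idxs = np.array([iv[2] for iv in intervals])
        pos = sub["pos"].to_numpy()
        k = np.searchsorted(starts, pos, side="right") - 1
        ok = (k >= 0) & (pos < ends[np.clip(k, 0, None)])
        if not ok.any():
            continue
        sub = sub.iloc[np.flatnonzero(ok)]
        hit = idxs[k[ok]]
        rows = np.array([frag_order[i] for i in hit], dtype=np.int64)
        cols = np.array([s_order[s] for s in sub["sample_id"]], dtype=np.int64)
        np.add.at(meth_mat, (rows, cols), sub["n_meth"].to_numpy())
        np.add.at(
            total_mat, (rows, cols), (sub["n_meth"] + sub["n_unmeth"]).to_numpy()
        )

    mask = total_mat >= min_reads
    with np.errstate(invalid="ignore", divide="ignore"):
        props = np.where(mask, meth_mat / np.where(total_mat == 0, 1, total_mat), np.nan)

    names = [fragments[i].name for i in keep_idx]
    meth_df = pd.DataFrame(props, index=names, columns=samples)
    cov_df = pd.DataFrame(total_mat, index=names, columns=samples)
    mask_df = pd.DataFrame(mask, index=names, columns=samples)

    if design is not None:
        keep_rows = np.ones(n_frag, dtype=bool)
        for group in design.groups:
            gsamples = [s for s in samples if design.group_of(s) == group]
            if gsamples:
                keep_rows &= (
                    mask_df[gsamples].sum(axis=1).to_numpy() >= min_samples_per_group
                )
            else:
                keep_rows[:] = False
        n_dropped = int((~keep_rows).sum())
        if n_dropped:
            logger.info(
                "dropped %d fragments failing the per-group coverage quorum", n_dropped
            )
        meth_df = meth_df.loc[keep_rows]
        cov_df = cov_df.loc[keep_rows]
        mask_df = mask_df.loc[keep_rows]
        keep_idx = [i for i, k in zip(keep_idx, keep_rows) if k]

    retained = FragmentSet(
        [fragments[i] for i in keep_idx],
        [fragments.cpg_positions[i] for i in keep_idx],
    )
    return FragmentMethMatrix(meth_df, cov_df, mask_df, fragments=retained)
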