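"""Pipeline orchestration: digest -> quantify -> annotate -> differential
methylation -> differential expression -> integration, with a JSON run
manifest recording the configuration, input checksums and per-stage
record counts so every reported number is traceable."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .annotation import GeneTable, RepeatAnnotation, classify_fragments, derive_elements
from .diffexpr import DifferentialExpression, load_expression
from .diffmeth import DifferentialMethylation, StudyDesign
from .integration import correlate_genes, integrate_dmf_deg, read_enhancers, regulator_correlogram
from .rrbs import Genome, load_meth_calls, mspi_digest, quantify_fragments

logger = logging.getLogger(__name__)

_CONFIG_FIELDS = {
    "genome",
    "genes",
    "repeats",
    "coverage_dir",
    "expression",
    "design",
    "enhancers",
    "outdir",
    "size_min",
    "size_max",
    "min_reads",
    "min_samples_per_group",
    "alpha_dmf",
    "delta_dmf",
    "coverage_weighted",
    "alpha_deg",
    "min_lfc",
    "eps",
    "promoter_upstream",
    "promoter_downstream",
    "min_repeat_overlap",
    "anchor_gene",
    "seed",
}


@dataclass
class RunConfig:
    """Paths and thresholds of one pipeline run; serialised verbatim into
    the manifest.  Unknown keys are rejected on load."""

    genome: str
    genes: str
    repeats: str
    coverage_dir: str
    expression: str
    design: str
    outdir: str
    enhancers: str | None = None
    size_min: int = 40
    size_max: int = 220
    min_reads: int = 10
    min_samples_per_group: int = 3
    alpha_dmf: float = 0.05
    delta_dmf: float = 0.25
    coverage_weighted: bool = False
    alpha_deg: float = 0.05
    min_lfc: float = 2.0
    eps: float = 1.0
    promoter_upstream: int = 5000
    promoter_downstream: int = 1000
    min_repeat_overlap: float = 0.5
    anchor_gene: str = "CD274"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _CONFIG_FIELDS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def validate(self) -> None:
        for key in ("genome", "genes", "repeats", "coverage_dir", "expression", "design"):
            path = getattr(self, key)
            if path is None or not Path(path).exists():
                raise FileNotFoundError(f"missing input {key!r}: {path}")
        if self.enhancers is not None and not Path(self.enhancers).exists():
            raise FileNotFoundError(f"missing input 'enhancers': {self.enhancers}")
        if self.size_min > self.size_max:
            raise ValueError("size_min > size_max")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Traceability record of one pipeline run."""

    config: dict[str, Any]
    input_checksums: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    version: str = ""
    started: str = ""
    finished: str = ""

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all computational stages and write every output table.

    Stages run strictly in order and communicate only through documented
    file formats or their in-memory equivalents; any stage error aborts
    with the stage name.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    for key in ("genome", "genes", "repeats", "expression", "design"):
        manifest.input_checksums[key] = _sha256(getattr(config, key))
    cov_files = sorted(Path(config.coverage_dir).glob("*.cov"))
    for f in cov_files:
        manifest.input_checksums[f"coverage/{f.name}"] = _sha256(f)

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("digest")
        genome = Genome.from_fasta(config.genome)
        fragments = mspi_digest(genome, (config.size_min, config.size_max))
        fragments.to_bed(outdir / "fragments.bed")
        manifest.counts["fragments"] = len(fragments)
    except Exception as exc:  # noqa: BLE001
        raise StageError("digest", exc) from exc

    try:
        stage("quantify")
        design = StudyDesign.from_tsv(config.design)
        calls = load_meth_calls({f.stem: f for f in cov_files})
        meth = quantify_fragments(
            calls,
            fragments,
            min_reads=config.min_reads,
            min_samples_per_group=config.min_samples_per_group,
            design=design,
        )
        meth.to_tsv(outdir / "fragment_meth.tsv")
        manifest.counts["fragments_quantified"] = meth.shape[0]
        manifest.counts["fragments_excluded"] = len(fragments) - meth.shape[0]
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("quantify", exc) from exc

    try:
        stage("annotate")
        genes = GeneTable.from_tsv(config.genes)
        repeats = RepeatAnnotation.from_bed(config.repeats)
        elements = derive_elements(
            genes, genome.lengths, config.promoter_upstream, config.promoter_downstream
        )
        labels = classify_fragments(
            meth.fragments, elements, repeats, config.min_repeat_overlap
        )
        labels.to_csv(outdir / "fragment_classes.tsv", sep="\t", index_label="fragment")
    except Exception as exc:  # noqa: BLE001
        raise StageError("annotate", exc) from exc

    try:
        stage("diffmeth")
        model = DifferentialMethylation(meth, design, labels)
        summary = model.global_summary()
        with open(outdir / "global_summary.json", "w") as fh:
            json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        dmf = model.fit(
            alpha=config.alpha_dmf,
            delta=config.delta_dmf,
            coverage_weighted=config.coverage_weighted,
        )
        dmf.to_tsv(outdir / "dmf_table.tsv")
        manifest.counts["fragments_tested"] = dmf.n_tested
        manifest.counts["fragments_skipped"] = dmf.n_skipped
        manifest.counts["dmfs"] = dmf.n_dmf
    except Exception as exc:  # noqa: BLE001
        raise StageError("diffmeth", exc) from exc

    try:
        stage("diffexpr")
        expr = load_expression(config.expression)
        deg = DifferentialExpression(expr, design).fit(
            alpha=config.alpha_deg, min_lfc=config.min_lfc, eps=config.eps
        )
        deg.to_tsv(outdir / "deg_table.tsv")
        manifest.counts["genes_tested"] = len(deg.table)
        manifest.counts["degs"] = deg.n_deg
    except Exception as exc:  # noqa: BLE001
        raise StageError("diffexpr", exc) from exc

    try:
        stage("integrate")
        enhancers = read_enhancers(config.enhancers) if config.enhancers else None
        records, concordance = integrate_dmf_deg(
            dmf.table,
            deg.degs,
            genes,
            enhancers,
            config.promoter_upstream,
            config.promoter_downstream,
        )
        records.to_csv(outdir / "integration_table.tsv", sep="\t", index=False)
        concordance.to_csv(outdir / "integration_concordance.tsv", sep="\t", index=False)
        manifest.counts["integration_records"] = len(records)
        manifest.counts["integration_genes"] = int(records["gene"].nunique()) if len(records) else 0

        global_meth = summary.per_sample_median
        if config.anchor_gene in expr.index:
            sidebar = correlate_genes(expr, config.anchor_gene, global_meth)
            sidebar.to_csv(outdir / "correlation_sidebar.tsv", sep="\t")
        correlogram = regulator_correlogram(
            expr, anchor_gene=config.anchor_gene if config.anchor_gene in expr.index else None,
            global_meth=global_meth,
        )
        correlogram.to_tsv(outdir / "correlogram.tsv")
        with open(outdir / "correlogram.json", "w") as fh:
            json.dump(correlogram.to_dict(), fh, indent=2)
            fh.write("\n")
    except Exception as exc:  # noqa: BLE001
        raise StageError("integrate", exc) from exc

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(outdir / "manifest.json")
    return manifest
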