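"""End-to-end pipeline with plain-file handoff and a reproducibility manifest.

Stages (each optional, each independently runnable on the previous stage's
files): simulate -> clean -> annotate -> de -> go_score -> compare.  All
intermediate artifacts are plain TSV/FASTA/JSON so every stage can be
inspected and rerun standalone; the manifest records parameters, seeds,
input checksums and per-stage row counts, and contains no timestamps, so
identical config + seed yields byte-identical output directories.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotate import attribute_all, build_tag_index, summarize_attribution
from .crossstudy import StudyGeneList, intersect_studies
from .de import call_significant, fc_histogram, frequency_classes
from .go import filter_and_compare, node_score, parse_obo, read_annotation_map
from .reference import ReferenceTranscriptome
from .simulate import SimConfig, simulate_tag_libraries, simulate_transcriptomes
from .tags import TagCountTable, clean_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage toggles and parameters; every field echoes its default."""

    outdir: str = "dualsage_run"
    seed: int = 0
    # stage toggles
    simulate: bool = True
    clean: bool = True
    annotate: bool = True
    de: bool = True
    go_score: bool = False
    compare: bool = False
    # inputs (used when the producing stage is disabled)
    counts: str | None = None
    host_fasta: str | None = None
    symbiont_fasta: str | None = None
    obo: str | None = None
    go_annotations: str | None = None
    study_lists: list[str] = field(default_factory=list)
    # parameters
    sim: dict = field(default_factory=dict)
    max_a_fraction: float = 0.8
    max_terminal_a_run: int = 15
    stringencies: list[int] = field(default_factory=lambda: [0, 2, 6])
    alpha: float = 0.05
    min_fc: float = 2.0
    log2_cut: float = 2.0
    test_method: str = "audic-claverie"
    bh: bool = False
    go_cutoff: float = 20.0
    go_level: int | None = None
    min_jaccard: float = 1.0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; return (and write) the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "dualsage",
        "version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "stages": [],
        "inputs": {},
        "row_counts": {},
    }

    table: TagCountTable | None = None
    host = symbiont = None

    if config.simulate:
        sim = SimConfig(**{"seed": config.seed, **config.sim})
        host, symbiont = simulate_transcriptomes(sim)
        table, truth = simulate_tag_libraries(sim, host, symbiont)
        host.to_fasta(out / "host.fasta")
        symbiont.to_fasta(out / "symbiont.fasta")
        table.to_tsv(out / "counts_raw.tsv")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        manifest["stages"].append("simulate")
        manifest["row_counts"]["simulate"] = {
            "host_transcripts": len(host),
            "symbiont_transcripts": len(symbiont),
            "tags": len(table),
        }
        logger.info("simulate: %d tags", len(table))

    if table is None and config.counts:
        table = TagCountTable.from_tsv(config.counts)
        manifest["inputs"]["counts"] = _sha256(Path(config.counts))
    if host is None and config.host_fasta:
        host = ReferenceTranscriptome.from_fasta(config.host_fasta, "host")
        manifest["inputs"]["host_fasta"] = _sha256(Path(config.host_fasta))
    if symbiont is None and config.symbiont_fasta:
        symbiont = ReferenceTranscriptome.from_fasta(config.symbiont_fasta, "symbiont")
        manifest["inputs"]["symbiont_fasta"] = _sha256(Path(config.symbiont_fasta))

    if config.clean:
        if table is None:
            raise FileNotFoundError("clean stage: no count table available")
        n_in = len(table)
        table, report = clean_table(
            table, config.max_a_fraction, config.max_terminal_a_run
        )
        table.to_tsv(out / "counts_clean.tsv")
        (out / "clean_report.json").write_text(json.dumps(report, indent=2))
        manifest["stages"].append("clean")
        manifest["row_counts"]["clean"] = report
        assert report["output_tags"] + report["removed_polya"] + report[
            "removed_singletons"
        ] == n_in
        logger.info("clean: %d -> %d tags", n_in, len(table))

    if config.annotate:
        if table is None or host is None or symbiont is None:
            raise FileNotFoundError("annotate stage: needs counts + two FASTAs")
        h_idx = build_tag_index(host)
        s_idx = build_tag_index(symbiont)
        attrib = attribute_all(
            table.tags.tolist(), h_idx, s_idx, tuple(config.stringencies)
        )
        attrib.to_csv(out / "attribution.tsv", sep="\t", index=False)
        for m, summ in summarize_attribution(attrib).items():
            summ.to_csv(out / f"annotation_summary_m{m}.tsv", sep="\t", index=False)
        manifest["stages"].append("annotate")
        manifest["row_counts"]["annotate"] = {"rows": len(attrib)}
        logger.info("annotate: %d attribution rows", len(attrib))

    if config.de:
        if table is None:
            raise FileNotFoundError("de stage: no count table available")
        results, summary = call_significant(
            table,
            alpha=config.alpha,
            min_fc=config.min_fc,
            log2_cut=config.log2_cut,
            method=config.test_method,
            bh=config.bh,
        )
        results.to_csv(out / "de_results.tsv", sep="\t", index=False)
        hist = fc_histogram(results)
        freq = frequency_classes(table)
        de_summary = {
            **dataclasses.asdict(summary),
            "fc_histogram": hist.to_dict("records"),
            "frequency_classes": freq.to_dict("records"),
        }
        (out / "de_summary.json").write_text(json.dumps(de_summary, indent=2))
        manifest["stages"].append("de")
        manifest["row_counts"]["de"] = dataclasses.asdict(summary)
        logger.info("de: %d significant of %d tags", summary.n_sig, summary.n_tags)

    if config.go_score:
        if not (config.obo and config.go_annotations):
            raise FileNotFoundError("go_score stage: needs --obo and annotation map")
        go = parse_obo(config.obo)
        manifest["inputs"]["obo"] = _sha256(Path(config.obo))
        annots = read_annotation_map(config.go_annotations)
        manifest["inputs"]["go_annotations"] = _sha256(Path(config.go_annotations))
        de_path = out / "de_results.tsv"
        if de_path.exists():
            import pandas as pd

            res = pd.read_csv(de_path, sep="\t")
            sig = set(res.loc[res["sig_log2gt2"], "tag"])
            annots = {k: v for k, v in annots.items() if k in sig}
        scores = node_score(go, annots)
        scores.to_csv(out / "go_scores.tsv", sep="\t", index=False)
        manifest["stages"].append("go_score")
        manifest["row_counts"]["go_score"] = {"terms": len(scores)}

    if config.compare:
        if len(config.study_lists) < 2:
            raise FileNotFoundError("compare stage: needs >= 2 study list files")
        lists = [StudyGeneList.from_tsv(p) for p in config.study_lists]
        for p in config.study_lists:
            manifest["inputs"][p] = _sha256(Path(p))
        result = intersect_studies(lists, min_jaccard=config.min_jaccard)
        result.core.to_csv(out / "core_functions.tsv", sep="\t", index=False)
        manifest["stages"].append("compare")
        manifest["row_counts"]["compare"] = {"core_functions": len(result.core)}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def compare_go_tables(host_scores, symbiont_scores, cutoff=20.0, level=None):
    """Convenience passthrough kept near the pipeline for CLI use."""
    return filter_and_compare(host_scores, symbiont_scores, cutoff, level)
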