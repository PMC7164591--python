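"""End-to-end orchestration: from genomes, reads and manifest to the
presence/co-occurrence table and the three-signal host-prediction report.

`analyze_study` is the in-memory engine; `run_all` is the file-driven
wrapper used by the CLI (reads a flat key=value config, loads every input,
writes every stage's TSV/JSON plus a run manifest). Reruns with the same
config are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cooccurrence import (
    DegenerateVectorError,
    abundance_correlation,
    average_replicates,
    binarize_tph,
    binary_cooccurrence,
    call_presence,
    host_prediction_report,
)
from .genome_features import detect_terminal_repeat, gc_content
from .io_core import ReadPair, SequenceRecord, read_fasta, read_fastq_pairs, read_manifest
from .kmer import kmer_null_comparison
from .mapping import (
    ReadBatch,
    ReferenceIndex,
    SampleAbundance,
    compute_abundance,
    map_reads,
    taxon_abundance,
)
from .spacers import SpacerRecord, match_spacers, read_spacers, summarize_candidate_hosts

logger = logging.getLogger("viromarker")


@dataclass
class PipelineConfig:
    """All knobs of a run; defaults are the pipeline's standard thresholds."""

    manifest: str = ""
    virus_fasta: str = ""
    hosts_fasta: str = ""
    spacer_table: str = ""
    pct_threshold: float = 0.01  # percent of library for presence
    breadth_threshold: float = 0.75
    use_breadth: bool = False  # survey mode: also require genome breadth
    tph_threshold: float = 125.0  # ppm quantification floor
    seed_len: int = 31
    min_identity: float = 0.95
    max_mismatches: int = 3
    kmer_k: int = 4
    n_shuffles: int = 3
    dtr_min_len: int = 20
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.pct_threshold <= 100:
            raise ValueError("pct_threshold must be in [0, 100]")
        if not 0 <= self.breadth_threshold <= 1:
            raise ValueError("breadth_threshold must be in [0, 1]")
        if self.tph_threshold < 0 or self.seed_len < 1 or not 0 < self.min_identity <= 1:
            raise ValueError("invalid mapper/threshold parameters")


_BOOL_KEYS = {"use_breadth"}


def load_config(path: str | Path) -> PipelineConfig:
    """Read a flat ``key = value`` config file ('#' starts a comment)."""
    fields = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    kwargs: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in fields:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        ftype = fields[key].type
        if key in _BOOL_KEYS:
            kwargs[key] = value.lower() in ("1", "true", "yes", "on")
        elif ftype == "int":
            kwargs[key] = int(value)
        elif ftype == "float":
            kwargs[key] = float(value)
        else:
            kwargs[key] = value
    config = PipelineConfig(**kwargs)
    config.validate()
    return config


@dataclass
class SampleInput:
    sample_id: str
    pairs: list[ReadPair]
    tph_ppm: float | None
    replicate_group: str


@dataclass
class StudyResult:
    per_sample: list[SampleAbundance]
    taxon_tables: dict[str, pd.DataFrame]  # sample_id -> per-taxon table
    study_table: pd.DataFrame
    phi: float | None
    phi_note: str
    n_positive_libraries: int
    n_positive_groups: int
    dtr_repeat_length: int
    virus_gc_percent: float
    spacer_hits: list
    spacer_summary: pd.DataFrame
    abundance_correlations: pd.DataFrame
    kmer_table: pd.DataFrame
    report: pd.DataFrame


def analyze_study(
    virus: SequenceRecord,
    samples: Sequence[SampleInput],
    hosts: Sequence[tuple[str, SequenceRecord]] = (),
    spacers: Sequence[SpacerRecord] = (),
    config: PipelineConfig | None = None,
) -> StudyResult:
    """Run every analysis stage on in-memory inputs."""
    config = config or PipelineConfig()
    config.validate()
    if not samples:
        raise ValueError("no samples supplied")

    logger.info("[dtr] scanning %s (%d bp)", virus.id, len(virus))
    dtr = detect_terminal_repeat(virus, min_len=config.dtr_min_len)
    gc_pct = 100.0 * gc_content(virus)

    virus_index = ReferenceIndex(virus, config.seed_len)
    host_indexes = [(t, ReferenceIndex(g, config.seed_len)) for t, g in hosts]

    per_sample: list[SampleAbundance] = []
    taxon_tables: dict[str, pd.DataFrame] = {}
    groups: dict[str, str] = {}
    tph_by_group: dict[str, float | None] = {}
    for s in samples:
        logger.info("[abundance] sample %s: %d pairs", s.sample_id, len(s.pairs))
        batch = ReadBatch(s.pairs)
        alignments = map_reads(batch, virus_index, config.seed_len, config.min_identity)
        per_sample.append(
            compute_abundance(alignments, batch.library_size, virus, sample_id=s.sample_id)
        )
        if host_indexes:
            taxon_tables[s.sample_id] = taxon_abundance(
                batch,
                [ix for _, ix in host_indexes],
                taxa=[t for t, _ in host_indexes],
                seed_len=config.seed_len,
                min_identity=config.min_identity,
            )
        groups[s.sample_id] = s.replicate_group
        if s.replicate_group not in tph_by_group or tph_by_group[s.replicate_group] is None:
            tph_by_group[s.replicate_group] = s.tph_ppm

    study = average_replicates(per_sample, groups)
    study["tph_ppm"] = [tph_by_group[g] for g in study["group"]]
    study["presence_flag"] = [
        call_presence(
            p,
            b,
            pct_threshold=config.pct_threshold,
            breadth_threshold=config.breadth_threshold,
            use_breadth=config.use_breadth,
        )
        for p, b in zip(study["percent_mapped"], study["breadth"])
    ]
    study["tph_flag"] = [binarize_tph(t, config.tph_threshold) for t in study["tph_ppm"]]

    # per-taxon abundances averaged over replicates, joined onto the table
    taxon_group_means: dict[str, pd.DataFrame] = {}
    if taxon_tables:
        long = pd.concat(
            [t.assign(group=groups[sid]) for sid, t in taxon_tables.items()],
            ignore_index=True,
        )
        means = (
            long.groupby(["group", "taxon"], sort=False)[["raw_reads", "percent_of_library"]]
            .mean()
            .reset_index()
        )
        for taxon in means["taxon"].unique():
            sub = means[means["taxon"] == taxon].set_index("group")
            study[f"pct_{taxon}"] = [sub["percent_of_library"].get(g, 0.0) for g in study["group"]]
            taxon_group_means[taxon] = sub

    n_pos_lib = sum(
        call_presence(
            s.percent_mapped,
            s.breadth,
            pct_threshold=config.pct_threshold,
            breadth_threshold=config.breadth_threshold,
            use_breadth=config.use_breadth,
        )
        for s in per_sample
    )
    n_pos_grp = int(study["presence_flag"].sum())

    phi: float | None
    try:
        phi = binary_cooccurrence(study["presence_flag"], study["tph_flag"])
        phi_note = "phi over replicate-averaged soil samples; thresholds inclusive (>=)"
    except DegenerateVectorError as exc:
        phi = None
        phi_note = f"degenerate: {exc}"

    # signal 1: CRISPR spacers
    hits = match_spacers(list(spacers), virus, config.max_mismatches) if spacers else []
    spacer_summary = summarize_candidate_hosts(hits)

    # signal 2: abundance-profile correlation per candidate taxon
    corr_rows = []
    virus_raw = study["mapped_reads_dedup"].to_numpy(dtype=float)
    virus_pct = study["percent_mapped"].to_numpy(dtype=float)
    for taxon, sub in taxon_group_means.items():
        raw = np.array([sub["raw_reads"].get(g, 0.0) for g in study["group"]])
        pct = np.array([sub["percent_of_library"].get(g, 0.0) for g in study["group"]])
        try:
            r_raw = abundance_correlation(virus_raw, raw, "raw")
            r_norm = abundance_correlation(virus_pct, pct, "normalized")
        except (DegenerateVectorError, ValueError):
            r_raw = r_norm = np.nan
        corr_rows.append({"taxon": taxon, "r_raw": r_raw, "r_normalized": r_norm})
    abundance_corr = pd.DataFrame(corr_rows, columns=["taxon", "r_raw", "r_normalized"])

    # signal 3: k-mer composition with shuffled-host null
    kmer_rows = []
    for i, (taxon, genome) in enumerate(hosts):
        logger.info("[kmer] %s vs %s (k=%d)", virus.id, taxon, config.kmer_k)
        r_real, null = kmer_null_comparison(
            virus, genome, k=config.kmer_k, n_shuffles=config.n_shuffles,
            seed=config.seed + i,
        )
        kmer_rows.append({"taxon": taxon, "kmer_r": r_real, "kmer_null_mean": null.mean})
    kmer_table = pd.DataFrame(kmer_rows, columns=["taxon", "kmer_r", "kmer_null_mean"])

    report = host_prediction_report(
        spacer_summary if not spacer_summary.empty else None,
        abundance_corr if not abundance_corr.empty else None,
        kmer_table if not kmer_table.empty else None,
    )

    return StudyResult(
        per_sample=per_sample,
        taxon_tables=taxon_tables,
        study_table=study,
        phi=phi,
        phi_note=phi_note,
        n_positive_libraries=n_pos_lib,
        n_positive_groups=n_pos_grp,
        dtr_repeat_length=dtr.repeat_length,
        virus_gc_percent=gc_pct,
        spacer_hits=hits,
        spacer_summary=spacer_summary,
        abundance_correlations=abundance_corr,
        kmer_table=kmer_table,
        report=report,
    )


def _parse_host_taxa(records: list[SequenceRecord]) -> list[tuple[str, SequenceRecord]]:
    """Taxon labels from ``taxon=...`` in FASTA descriptions, else record ids."""
    out = []
    for r in records:
        taxon = r.id
        for token in r.description.split():
            if token.startswith("taxon="):
                taxon = token[len("taxon="):]
        out.append((taxon, r))
    return out


def load_samples(config: PipelineConfig) -> list[SampleInput]:
    rows = read_manifest(config.manifest)
    return [
        SampleInput(
            sample_id=row.sample_id,
            pairs=list(read_fastq_pairs(row.fastq1, row.fastq2)),
            tph_ppm=row.tph_ppm,
            replicate_group=row.replicate_group,
        )
        for row in rows
    ]


def run_all(config: PipelineConfig, outdir: str | Path) -> Path:
    """File-driven pipeline run; writes every stage's outputs to ``outdir``."""
    config.validate()
    for label, path in (("manifest", config.manifest), ("virus_fasta", config.virus_fasta)):
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"{label} not found: {path!r}")
    virus = read_fasta(config.virus_fasta)[0]
    hosts = (
        _parse_host_taxa(read_fasta(config.hosts_fasta))
        if config.hosts_fasta and Path(config.hosts_fasta).exists()
        else []
    )
    spacers = (
        read_spacers(config.spacer_table)
        if config.spacer_table and Path(config.spacer_table).exists()
        else []
    )
    samples = load_samples(config)
    result = analyze_study(virus, samples, hosts=hosts, spacers=spacers, config=config)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([dataclasses.asdict(s) for s in result.per_sample]).to_csv(
        outdir / "abundance_per_library.tsv", sep="\t", index=False
    )
    result.study_table.to_csv(outdir / "study_table.tsv", sep="\t", index=False)
    pd.DataFrame([h.__dict__ for h in result.spacer_hits]).to_csv(
        outdir / "spacer_hits.tsv", sep="\t", index=False
    )
    result.spacer_summary.to_csv(outdir / "spacer_summary.tsv", sep="\t", index=False)
    result.kmer_table.to_csv(outdir / "kmer_host.tsv", sep="\t", index=False)
    result.abundance_correlations.to_csv(
        outdir / "abundance_correlations.tsv", sep="\t", index=False
    )
    report = result.report.copy()
    for col in ("spacer_hits", "r_raw", "r_normalized", "kmer_r", "kmer_null_mean"):
        report[col] = report[col].map(lambda v: "n.d." if pd.isna(v) else v)
    report.to_csv(outdir / "host_prediction.tsv", sep="\t", index=False)
    summary = {
        "phi": result.phi,
        "phi_note": result.phi_note,
        "n_samples": len(result.study_table),
        "n_libraries": len(result.per_sample),
        "n_positive_libraries": result.n_positive_libraries,
        "n_positive_groups": result.n_positive_groups,
        "dtr_repeat_length": result.dtr_repeat_length,
        "virus_gc_percent": result.virus_gc_percent,
        "thresholds": {
            "pct": config.pct_threshold,
            "breadth": config.breadth_threshold if config.use_breadth else None,
            "tph_ppm": config.tph_threshold,
            "convention": "inclusive (>=)",
        },
        "version": __version__,
        "config": dataclasses.asdict(config),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    with open(outdir / "run_config.txt", "w") as fh:
        for f in dataclasses.fields(config):
            fh.write(f"{f.name} = {getattr(config, f.name)}\n")
    return outdir
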