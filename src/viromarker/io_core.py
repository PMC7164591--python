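"""Readers and writers for the formats the pipeline touches.

FASTA and FASTQ go through Biopython; the sample manifest is a headered TSV
read with pandas. Residue alphabets are strict: only {A,C,G,T,N} (any case)
are accepted in genome FASTA — RNA-style U is rejected rather than silently
converted. Missing TPH concentrations stay missing: the analyzer these
measurements come from has a 125 ppm quantification floor, so "no value" is
not the same datum as zero.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

_VALID_RESIDUES = frozenset("ACGTN")
_MATE_SUFFIX = re.compile(r"/[12]$")

MANIFEST_COLUMNS = ["sample_id", "fastq1", "fastq2", "tph_ppm", "replicate_group"]


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A,C,G,T,N}, upper-cased."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id must be non-empty without whitespace: {self.id!r}")
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            pos = next(i for i, c in enumerate(self.residues) if c in bad)
            raise ValueError(
                f"invalid residue {self.residues[pos]!r} at position {pos} in record {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ReadPair:
    """One paired-end fragment: two mates with their quality strings."""

    read_id: str
    mate1: str
    mate2: str
    qual1: str = ""
    qual2: str = ""

    def __post_init__(self) -> None:
        if self.qual1 and len(self.qual1) != len(self.mate1):
            raise ValueError(f"mate1/qual1 length mismatch for read {self.read_id!r}")
        if self.qual2 and len(self.qual2) != len(self.mate2):
            raise ValueError(f"mate2/qual2 length mismatch for read {self.read_id!r}")


@dataclass(frozen=True)
class SampleManifestRow:
    sample_id: str
    fastq1: str
    fastq2: str
    tph_ppm: float | None
    replicate_group: str


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read all records of a (multi-)FASTA file, validating the alphabet."""
    with _open_text(path) as handle:
        records = [
            SequenceRecord(id=r.id, residues=str(r.seq), description=r.description)
            for r in SeqIO.parse(handle, "fasta")
        ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records wrapped at 70 columns."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with _open_text(path, "wt") as handle:
        FastaWriter(handle, wrap=70).write_file(bio)


def _strip_mate_suffix(title: str) -> str:
    name = title.split()[0]
    return _MATE_SUFFIX.sub("", name)


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    """Stream read pairs from two parallel FASTQ files (.gz by suffix).

    Mate ids (after stripping a trailing ``/1`` / ``/2``) must agree record
    by record, and both files must hold the same number of records.
    """
    with _open_text(path1) as h1, _open_text(path2) as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        n = 0
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                return
            n += 1
            if rec1 is None or rec2 is None:
                raise ValueError(
                    f"unequal record counts: {path1} and {path2} diverge at record {n}"
                )
            id1 = _strip_mate_suffix(rec1[0])
            id2 = _strip_mate_suffix(rec2[0])
            if id1 != id2:
                raise ValueError(f"read id mismatch at record {n}: {id1!r} vs {id2!r}")
            yield ReadPair(read_id=id1, mate1=rec1[1], mate2=rec2[1], qual1=rec1[2], qual2=rec2[2])


def write_fastq_pair(pairs: Iterable[ReadPair], path1: str | Path, path2: str | Path) -> None:
    """Write mates to two parallel FASTQ files, never line-wrapped."""
    with _open_text(path1, "wt") as h1, _open_text(path2, "wt") as h2:
        for p in pairs:
            q1 = p.qual1 or "I" * len(p.mate1)
            q2 = p.qual2 or "I" * len(p.mate2)
            h1.write(f"@{p.read_id}/1\n{p.mate1}\n+\n{q1}\n")
            h2.write(f"@{p.read_id}/2\n{p.mate2}\n+\n{q2}\n")


def read_manifest(path: str | Path) -> list[SampleManifestRow]:
    """Read the sample manifest TSV (header required, UTF-8).

    Columns: sample_id, fastq1, fastq2, tph_ppm, replicate_group. An empty
    tph_ppm field is a missing value, distinct from 0.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks required columns: {missing}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate sample_id in manifest: {sorted(set(dup))}")
    rows = []
    for rec in df.itertuples(index=False):
        tph: float | None
        raw = rec.tph_ppm.strip()
        if raw == "":
            tph = None
        else:
            tph = float(raw)
            if tph < 0:
                raise ValueError(f"negative tph_ppm for sample {rec.sample_id!r}: {tph}")
        rows.append(
            SampleManifestRow(
                sample_id=rec.sample_id,
                fastq1=rec.fastq1,
                fastq2=rec.fastq2,
                tph_ppm=tph,
                replicate_group=rec.replicate_group,
            )
        )
    return rows


def write_manifest(rows: Iterable[SampleManifestRow], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "fastq1": r.fastq1,
                "fastq2": r.fastq2,
                "tph_ppm": "" if r.tph_ppm is None else r.tph_ppm,
                "replicate_group": r.replicate_group,
            }
            for r in rows
        ],
        columns=MANIFEST_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
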