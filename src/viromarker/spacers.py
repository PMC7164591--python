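"""CRISPR spacer matching against a viral genome.

A spacer stored in a prokaryote's CRISPR array is a copy of a segment of a
virus that once infected it, so an (near-)exact match of a spacer of known
taxonomic origin inside a viral genome ties the virus to that taxon. The
search is an ungapped sliding-window Hamming scan of every spacer against
both strands of the virus; every position within the mismatch budget is
reported (no greedy masking of overlaps), and minus-strand hits carry the
forward-strand coordinate of the matched window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from . import _seqcodes
from .io_core import SequenceRecord, _open_text

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = ["taxon", "n_hits", "n_distinct_spacers", "best_mismatches"]


@dataclass(frozen=True)
class SpacerRecord:
    spacer_id: str
    taxon: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"spacer {self.spacer_id!r} has an empty sequence")
        bad = set(self.residues.upper()) - set("ACGT")
        if bad:
            raise ValueError(f"spacer {self.spacer_id!r} has invalid residues {sorted(bad)}")
        object.__setattr__(self, "residues", self.residues.upper())


@dataclass(frozen=True)
class SpacerHit:
    spacer_id: str
    taxon: str
    position: int  # 0-based start on the virus forward strand
    strand: str  # "+" or "-"
    mismatches: int


def read_spacers(path: str | Path) -> list[SpacerRecord]:
    """Load spacers from FASTA (headers ``spacer_id|taxon``) or 3-column TSV.

    Spacers containing N (or other ambiguity codes) are dropped; the number
    dropped is logged as a warning.
    """
    path = Path(path)
    rows: list[tuple[str, str, str]] = []
    with _open_text(path) as handle:
        first = handle.read(1)
        handle.seek(0)
        if first == ">":
            from Bio import SeqIO

            for rec in SeqIO.parse(handle, "fasta"):
                sid, _, taxon = rec.id.partition("|")
                rows.append((sid, taxon or "unknown", str(rec.seq)))
        else:
            df = pd.read_csv(handle, sep="\t", dtype=str)
            cols = list(df.columns[:3])
            for rec in df.itertuples(index=False):
                rows.append((str(rec[0]), str(rec[1]), str(rec[2])))
    spacers = []
    n_rejected = 0
    for sid, taxon, seq in rows:
        try:
            spacers.append(SpacerRecord(spacer_id=sid, taxon=taxon, residues=seq))
        except ValueError:
            n_rejected += 1
    if n_rejected:
        logger.warning("rejected %d spacers with ambiguous residues from %s", n_rejected, path)
    return spacers


def _hamming_scan(virus_codes: np.ndarray, spacer_codes: np.ndarray) -> np.ndarray:
    """Mismatch count of the spacer against every window of the virus.

    Windows containing an N in the virus are reported as ``m + 1`` (the
    spacer length plus one) so they can never satisfy any mismatch budget.
    """
    m = spacer_codes.size
    windows = sliding_window_view(virus_codes, m)
    mism = (windows != spacer_codes).sum(axis=1)
    mism[(windows >= _seqcodes.CODE_N).any(axis=1)] = m + 1
    return mism


def match_spacers(
    spacers: list[SpacerRecord],
    virus: SequenceRecord,
    max_mismatches: int = 3,
) -> list[SpacerHit]:
    """All placements of each spacer on either strand within the budget."""
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    virus_codes = _seqcodes.encode(virus.residues)
    hits: list[SpacerHit] = []
    for sp in spacers:
        sp_codes = _seqcodes.encode(sp.residues)
        if sp_codes.size > virus_codes.size:
            logger.warning(
                "spacer %s (%d bp) longer than virus %s (%d bp); skipped",
                sp.spacer_id, sp_codes.size, virus.id, virus_codes.size,
            )
            continue
        for strand, probe in (("+", sp_codes), ("-", _seqcodes.revcomp_codes(sp_codes))):
            mism = _hamming_scan(virus_codes, probe)
            for pos in np.nonzero(mism <= max_mismatches)[0]:
                hits.append(
                    SpacerHit(
                        spacer_id=sp.spacer_id,
                        taxon=sp.taxon,
                        position=int(pos),
                        strand=strand,
                        mismatches=int(mism[pos]),
                    )
                )
    hits.sort(key=lambda h: (h.spacer_id, h.position, h.strand))
    return hits


def summarize_candidate_hosts(hits: list[SpacerHit]) -> pd.DataFrame:
    """Per-taxon hit summary, strongest candidates first.

    Sorted by (n_hits desc, best_mismatches asc, taxon asc).
    """
    if not hits:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    df = pd.DataFrame([h.__dict__ for h in hits])
    summary = (
        df.groupby("taxon")
        .agg(
            n_hits=("spacer_id", "size"),
            n_distinct_spacers=("spacer_id", "nunique"),
            best_mismatches=("mismatches", "min"),
        )
        .reset_index()
    )
    summary = summary.sort_values(
        ["n_hits", "best_mismatches", "taxon"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return summary[SUMMARY_COLUMNS]
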