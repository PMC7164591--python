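"""Presence calling, binarization and correlation analyses.

The survey logic: a sample is scored virus-positive when the library-size
normalized mapped-read percentage reaches 0.01% (optionally also requiring
75% genome breadth, the rule used when screening public archives), and
pollution-positive when the TPH concentration reaches the 125 ppm
quantification floor of the analyzer. The binary co-occurrence statistic is
the phi coefficient, i.e. the Pearson correlation of two 0/1 vectors,
computed exactly from the 2x2 contingency table. All thresholds are
inclusive (>=); a missing TPH value means "below quantification" and is
scored non-polluted.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mapping import SampleAbundance

PCT_THRESHOLD = 0.01  # percent of library
BREADTH_THRESHOLD = 0.75
TPH_THRESHOLD = 125.0  # ppm


class DegenerateVectorError(ValueError):
    """Raised when a correlation input is constant (no number is emitted)."""


def average_replicates(
    per_sample: Sequence[SampleAbundance],
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Mean normalized abundance per replicate group.

    Each library's percent_mapped (and breadth, mean depth, dedup count) is
    averaged across the DNA-isolation replicates of the same soil sample;
    normalization happens before averaging.
    """
    missing = [s.sample_id for s in per_sample if s.sample_id not in groups]
    if missing:
        raise ValueError(f"samples without a replicate group: {missing}")
    if not per_sample:
        raise ValueError("no samples to average")
    df = pd.DataFrame(
        {
            "group": [groups[s.sample_id] for s in per_sample],
            "percent_mapped": [s.percent_mapped for s in per_sample],
            "breadth": [s.breadth for s in per_sample],
            "mean_depth": [s.mean_depth for s in per_sample],
            "mapped_reads_dedup": [s.mapped_reads_dedup for s in per_sample],
            "n_replicates": 1,
        }
    )
    out = (
        df.groupby("group", sort=False)
        .agg(
            percent_mapped=("percent_mapped", "mean"),
            breadth=("breadth", "mean"),
            mean_depth=("mean_depth", "mean"),
            mapped_reads_dedup=("mapped_reads_dedup", "mean"),
            n_replicates=("n_replicates", "sum"),
        )
        .reset_index()
    )
    return out


def call_presence(
    percent_mapped: float,
    breadth: float = 1.0,
    pct_threshold: float = PCT_THRESHOLD,
    breadth_threshold: float = BREADTH_THRESHOLD,
    use_breadth: bool = False,
) -> int:
    """1 if the virus is called present in the sample, else 0."""
    present = percent_mapped >= pct_threshold
    if use_breadth:
        present = present and breadth >= breadth_threshold
    return int(present)


def binarize_tph(tph_ppm: float | None, threshold: float = TPH_THRESHOLD) -> int:
    """1 if quantified at or above the threshold; missing scores 0."""
    if tph_ppm is None or (isinstance(tph_ppm, float) and math.isnan(tph_ppm)):
        return 0
    return int(tph_ppm >= threshold)


def binary_cooccurrence(presence: Sequence[int], pollution: Sequence[int]) -> float:
    """Phi coefficient of two 0/1 vectors.

    phi = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)) over the 2x2 contingency
    table; algebraically identical to the Pearson correlation of the two
    binary vectors, but exact on integer tables.
    """
    x = np.asarray(presence, dtype=np.int64)
    y = np.asarray(pollution, dtype=np.int64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("presence and pollution must be equal-length vectors (n >= 2)")
    if set(np.unique(x)) - {0, 1} or set(np.unique(y)) - {0, 1}:
        raise ValueError("inputs must be binary 0/1 vectors")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateVectorError("constant binary vector: phi is undefined")
    a = int(np.sum((x == 1) & (y == 1)))
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    d = int(np.sum((x == 0) & (y == 0)))
    return (a * d - b * c) / math.sqrt((a + b) * (c + d) * (a + c) * (b + d))


def abundance_correlation(
    virus: Sequence[float], host: Sequence[float], mode: str = "normalized"
) -> float:
    """Pearson correlation between per-sample virus and host abundances.

    ``mode`` is documentation of what the caller passed: "raw" for
    deduplicated mapped-read counts, "normalized" for percent-of-library
    values. The estimator is the same either way.
    """
    if mode not in ("raw", "normalized"):
        raise ValueError(f"unknown mode {mode!r}")
    x = np.asarray(virus, dtype=float)
    y = np.asarray(host, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateVectorError("constant abundance vector: r is undefined")
    return float(stats.pearsonr(x, y).statistic)


def host_prediction_report(
    spacer_summary: pd.DataFrame | None = None,
    abundance_correlations: pd.DataFrame | None = None,
    kmer_results: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge the three host-prediction signals into one per-taxon table.

    Inputs are per-taxon tables: the spacer summary (taxon, n_hits, ...),
    abundance correlations (taxon, r_raw, r_normalized) and k-mer results
    (taxon, kmer_r, kmer_null_mean). Missing signals appear as NaN and are
    rendered "n.d." in text output. A taxon is flagged ``consistent`` only
    when every signal that is present ranks it first.
    """
    frames = []
    tops = []
    if spacer_summary is not None and not spacer_summary.empty:
        s = spacer_summary.rename(columns={"n_hits": "spacer_hits"})
        frames.append(s[["taxon", "spacer_hits"]])
        tops.append(s.iloc[0]["taxon"])
    if abundance_correlations is not None and not abundance_correlations.empty:
        a = abundance_correlations
        frames.append(a[["taxon", "r_raw", "r_normalized"]])
        if a["r_normalized"].notna().any():
            tops.append(a.loc[a["r_normalized"].idxmax(), "taxon"])
    if kmer_results is not None and not kmer_results.empty:
        km = kmer_results
        frames.append(km[["taxon", "kmer_r", "kmer_null_mean"]])
        if km["kmer_r"].notna().any():
            tops.append(km.loc[km["kmer_r"].idxmax(), "taxon"])
    if not frames:
        raise ValueError("at least one host-prediction signal is required")
    report = frames[0].copy()
    for f in frames[1:]:
        report = report.merge(f, on="taxon", how="outer")
    for col in ("spacer_hits", "r_raw", "r_normalized", "kmer_r", "kmer_null_mean"):
        if col not in report.columns:
            report[col] = np.nan
    report["consistent"] = False
    if len(tops) >= 2 and len(set(tops)) == 1:
        report.loc[report["taxon"] == tops[0], "consistent"] = True
    sort_key = report["spacer_hits"].fillna(-1)
    report = (
        report.assign(_k=sort_key)
        .sort_values(["_k", "r_normalized"], ascending=[False, False], na_position="last")
        .drop(columns="_k")
        .reset_index(drop=True)
    )
    return report[
        ["taxon", "spacer_hits", "r_raw", "r_normalized", "kmer_r", "kmer_null_mean", "consistent"]
    ]
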