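"""Synthetic study generator.

Everything the analysis assumes about real data is planted here with known
ground truth: a circular-style viral genome with a direct terminal repeat,
a host genome sharing the virus's higher-order composition and carrying a
CRISPR array of virus-derived spacers, decoy host genomes with unrelated
composition, and multi-sample paired-end shotgun libraries in which the
viral read fraction tracks a binary pollution label and the true host's
abundance tracks the viral fraction.

Genome composition is an order-``o`` Markov chain over {A,C,G,T}; reads are
substitution-only (no indels), matching the ungapped mapper. All generators
are deterministic per (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _seqcodes
from .io_core import (
    ReadPair,
    SampleManifestRow,
    SequenceRecord,
    write_fasta,
    write_fastq_pair,
    write_manifest,
)
from .spacers import SpacerRecord

# default scales mirror the genome the pipeline was developed around
VIRUS_LENGTH = 67_826
DTR_LENGTH = 8_697

# a generic CRISPR direct-repeat unit used between planted spacers
DEFAULT_REPEAT_UNIT = "GTTTCAATCCACGCACCCATCAGGGATTGAAAC"

PLANTED_HOST_TAXON = "Methanosarcina"
DECOY_TAXA = ("Methanocaldococcus", "Tannerella")

# coupled-mode viral fractions for polluted samples (strong / weak / trace)
COUPLED_VIRAL_FRACTIONS = (0.084, 0.008, 0.001)


@dataclass(frozen=True)
class CompositionModel:
    """Order-``order`` Markov model over {A,C,G,T}."""

    order: int
    probs: np.ndarray  # shape (4**order, 4), rows sum to 1

    def __post_init__(self) -> None:
        expected = (4**self.order, 4)
        if self.probs.shape != expected:
            raise ValueError(f"probs must have shape {expected}, got {self.probs.shape}")
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every conditional distribution must sum to 1")

    @classmethod
    def uniform(cls, order: int = 0) -> "CompositionModel":
        return cls(order=order, probs=np.full((4**order, 4), 0.25))

    @classmethod
    def from_base_probs(cls, p: tuple[float, float, float, float]) -> "CompositionModel":
        return cls(order=0, probs=np.array([p], dtype=float))

    @classmethod
    def random_skewed(
        cls, order: int = 3, seed: int = 0, concentration: float = 1.0
    ) -> "CompositionModel":
        """Random conditionals drawn from a symmetric Dirichlet.

        Lower ``concentration`` gives stronger k-mer skew and hence a
        stronger composition signature shared by genomes of the model.
        """
        rng = np.random.default_rng(seed)
        probs = rng.dirichlet([concentration] * 4, size=4**order)
        return cls(order=order, probs=probs)


@dataclass
class StudyGroundTruth:
    pollution: dict[str, int]  # soil-sample id -> 0/1
    viral_fraction: dict[str, float]  # soil-sample id -> planted fraction
    host_fractions: dict[str, dict[str, float]]  # taxon -> sample -> fraction
    spacer_positions: dict[str, int]  # spacer_id -> 0-based protospacer start
    crispr_insert_position: int
    dtr_length: int
    planted_host_taxon: str
    seed: int


@dataclass
class StudySample:
    sample_id: str
    replicate_group: str
    tph_ppm: float | None
    pairs: list[ReadPair]
    truth_pairs: dict[str, int]  # reference id -> original pair count
    truth_duplicates: dict[str, int]


@dataclass
class Study:
    virus: SequenceRecord
    hosts: list[tuple[str, SequenceRecord]]  # (taxon, genome)
    background: SequenceRecord
    spacers: list[SpacerRecord]
    samples: list[StudySample]
    ground_truth: StudyGroundTruth


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(2**31, size=n)]


def generate_genome(
    length: int, model: CompositionModel, seed: int, genome_id: str = "genome"
) -> SequenceRecord:
    """Sample a genome of ``length`` bases from the composition model."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    cp = np.cumsum(model.probs, axis=1).tolist()
    n_states = 4**model.order
    mask = n_states - 1
    ctx = int(rng.integers(n_states))
    u = rng.random(length)
    out = np.empty(length, dtype=np.uint8)
    for i in range(length):
        row = cp[ctx]
        x = u[i]
        b = 0 if x < row[0] else 1 if x < row[1] else 2 if x < row[2] else 3
        out[i] = b
        ctx = ((ctx << 2) | b) & mask
    return SequenceRecord(id=genome_id, residues=_seqcodes.decode(out))


def generate_virus(
    length: int = VIRUS_LENGTH,
    model: CompositionModel | None = None,
    dtr_len: int = DTR_LENGTH,
    seed: int = 0,
    genome_id: str = "virus",
) -> SequenceRecord:
    """Viral genome whose first and last ``dtr_len`` bases are identical."""
    if dtr_len < 0 or dtr_len > length // 2:
        raise ValueError(f"dtr_len must be in [0, length//2], got {dtr_len}")
    if model is None:
        model = CompositionModel.random_skewed(order=3, seed=seed)
    core = generate_genome(length - dtr_len, model, seed, genome_id=genome_id)
    residues = core.residues + core.residues[:dtr_len]
    return SequenceRecord(id=genome_id, residues=residues, description=core.description)


def plant_crispr_array(
    host: SequenceRecord,
    virus: SequenceRecord,
    n_spacers: int = 5,
    spacer_len: int = 35,
    repeat_unit: str = DEFAULT_REPEAT_UNIT,
    seed: int = 0,
    taxon: str = PLANTED_HOST_TAXON,
) -> tuple[SequenceRecord, list[SpacerRecord], dict]:
    """Insert a CRISPR array of virus-derived spacers into the host genome.

    ``n_spacers`` distinct windows of the virus become spacers interleaved
    with ``repeat_unit``; the array is inserted at one random host position.
    Returns the modified host, the spacer table, and a ground-truth dict
    with the protospacer coordinates and the insertion point.
    """
    if n_spacers < 1:
        raise ValueError("n_spacers must be >= 1")
    if len(virus) < spacer_len:
        raise ValueError("virus shorter than spacer_len")
    n_positions = len(virus) - spacer_len + 1
    if n_spacers > n_positions:
        raise ValueError(f"cannot sample {n_spacers} distinct spacers from {n_positions} windows")
    rng = np.random.default_rng(seed)
    starts = rng.choice(n_positions, size=n_spacers, replace=False)
    spacers = []
    positions = {}
    array_parts = [repeat_unit]
    for i, s in enumerate(sorted(int(x) for x in starts)):
        sid = f"{taxon}_spacer_{i + 1}"
        seq = virus.residues[s : s + spacer_len]
        spacers.append(SpacerRecord(spacer_id=sid, taxon=taxon, residues=seq))
        positions[sid] = s
        array_parts.extend((seq, repeat_unit))
    array = "".join(array_parts)
    insert_at = int(rng.integers(len(host) + 1))
    residues = host.residues[:insert_at] + array + host.residues[insert_at:]
    new_host = SequenceRecord(id=host.id, residues=residues, description=host.description)
    truth = {"spacer_positions": positions, "insert_position": insert_at}
    return new_host, spacers, truth


def simulate_sample(
    refs: list[tuple[SequenceRecord, float]],
    n_pairs: int,
    read_len: int = 150,
    insert_mean: float = 350.0,
    insert_sd: float = 35.0,
    error_rate: float = 0.005,
    duplicate_rate: float = 0.0,
    seed: int = 0,
    background: SequenceRecord | None = None,
    id_prefix: str = "r",
) -> tuple[list[ReadPair], dict]:
    """Simulate one paired-end library.

    Fragments are sampled uniformly from each reference in the given
    proportions; the remainder of the library comes from ``background`` (an
    unrelated genome standing in for the unassigned majority of a real
    metagenome). Mates read inward from opposite fragment ends; substitution
    errors occur per base at ``error_rate``; a ``duplicate_rate`` fraction
    of pairs is emitted twice (same coordinates and residues, fresh ids).

    Returns (pairs, truth) where truth records original pair counts and
    duplicate counts per reference id.
    """
    if not 0 <= error_rate < 1 or not 0 <= duplicate_rate < 1:
        raise ValueError("error_rate and duplicate_rate must be in [0, 1)")
    if insert_mean < read_len:
        raise ValueError("insert_mean must be >= read_len")
    fractions = [f for _, f in refs]
    if any(f < 0 for f in fractions) or sum(fractions) > 1 + 1e-9:
        raise ValueError("reference fractions must be non-negative and sum to <= 1")
    rng = np.random.default_rng(seed)
    bg_fraction = max(0.0, 1.0 - sum(fractions))
    sources = list(refs)
    if bg_fraction > 1e-12:
        if background is None:
            background = generate_genome(
                50_000, CompositionModel.uniform(), int(rng.integers(2**31)), "background"
            )
        sources.append((background, bg_fraction))
    probs = np.array([f for _, f in sources], dtype=float)
    probs = probs / probs.sum()
    counts = rng.multinomial(n_pairs, probs)

    comp = np.array([3, 2, 1, 0, _seqcodes.CODE_N], dtype=np.uint8)
    pairs: list[ReadPair] = []
    truth_pairs: dict[str, int] = {}
    for (ref, _), cnt in zip(sources, counts):
        truth_pairs[ref.id] = int(cnt)
        if cnt == 0:
            continue
        ref_codes = _seqcodes.encode(ref.residues)
        n = ref_codes.size
        if n < read_len:
            raise ValueError(f"reference {ref.id!r} shorter than read length")
        max_insert = min(n, int(insert_mean + 6 * insert_sd))
        inserts = np.clip(
            np.rint(rng.normal(insert_mean, insert_sd, size=cnt)).astype(np.int64),
            read_len,
            max_insert,
        )
        pos = np.floor(rng.random(cnt) * (n - inserts + 1)).astype(np.int64)
        span = np.arange(read_len, dtype=np.int64)
        m1 = ref_codes[pos[:, None] + span]
        ends = pos + inserts
        m2 = comp[ref_codes[(ends - read_len)[:, None] + span]][:, ::-1]
        # substitution errors: replace with one of the three other bases
        for mat in (m1, m2):
            mask = rng.random(mat.shape) < error_rate
            n_err = int(mask.sum())
            if n_err:
                mat[mask] = (mat[mask] + rng.integers(1, 4, size=n_err).astype(np.uint8)) % 4
        flip = rng.random(cnt) < 0.5  # fragment sampled from the minus strand
        qual = "I" * read_len
        for i in range(cnt):
            a, b = (m2[i], m1[i]) if flip[i] else (m1[i], m2[i])
            pairs.append(
                ReadPair(
                    read_id=f"{id_prefix}_{ref.id}_{i}",
                    mate1=_seqcodes.decode(a),
                    mate2=_seqcodes.decode(b),
                    qual1=qual,
                    qual2=qual,
                )
            )
    truth_duplicates: dict[str, int] = {rid: 0 for rid in truth_pairs}
    n_dup = int(rng.binomial(n_pairs, duplicate_rate))
    if n_dup:
        dup_idx = rng.choice(len(pairs), size=min(n_dup, len(pairs)), replace=False)
        for j, i in enumerate(sorted(int(x) for x in dup_idx)):
            p = pairs[i]
            ref_id = p.read_id[len(id_prefix) + 1 :].rsplit("_", 1)[0]
            truth_duplicates[ref_id] += 1
            pairs.append(
                ReadPair(
                    read_id=f"{id_prefix}_dup_{j}",
                    mate1=p.mate1,
                    mate2=p.mate2,
                    qual1=p.qual1,
                    qual2=p.qual2,
                )
            )
    perm = rng.permutation(len(pairs))
    pairs = [pairs[int(i)] for i in perm]
    return pairs, {"pairs": truth_pairs, "duplicates": truth_duplicates}


def _pollution_labels(n_samples: int) -> list[int]:
    """Survey layout: locations x 3 depths; the deep sample of every
    location except the control (third) location is polluted."""
    labels = []
    for i in range(n_samples):
        location, depth = divmod(i, 3)
        labels.append(1 if depth == 2 and location != 2 else 0)
    return labels


def generate_study(
    n_samples: int = 12,
    coupling: str = "coupled",
    seed: int = 0,
    n_pairs: int = 2500,
    read_len: int = 150,
    error_rate: float = 0.005,
    duplicate_rate: float = 0.05,
    n_replicates: int = 1,
    virus_length: int = VIRUS_LENGTH,
    dtr_len: int = DTR_LENGTH,
    host_genome_length: int = 40_000,
    n_decoys: int = 2,
    n_spacers: int = 5,
    host_only: bool = False,
) -> Study:
    """Generate a full multi-sample study with ground truth.

    ``coupling="coupled"`` plants the virus (fractions 8.4%/0.8%/0.1%, all
    above the 0.01% presence threshold) exactly in the polluted samples and
    makes the true host's fraction an affine function of the viral fraction
    plus noise. ``coupling="independent"`` draws presence i.i.d. with
    probability 1/2 per sample, regardless of pollution (the maximum-entropy
    null over presence patterns). ``host_only=True`` skips decoy genomes and
    spacers (used for presence-only analyses).
    """
    if n_samples < 4:
        raise ValueError("n_samples must be >= 4")
    if coupling not in ("coupled", "independent"):
        raise ValueError(f"unknown coupling {coupling!r}")
    seeds = _child_seeds(seed, 8 + n_samples * n_replicates)
    shared_model = CompositionModel.random_skewed(order=3, seed=seeds[0])
    virus = generate_virus(virus_length, shared_model, dtr_len, seeds[1], genome_id="virus")
    host = generate_genome(
        host_genome_length, shared_model, seeds[2], genome_id="host_methanosarcina"
    )
    host, spacers, crispr_truth = plant_crispr_array(
        host, virus, n_spacers=n_spacers, seed=seeds[3], taxon=PLANTED_HOST_TAXON
    )
    hosts: list[tuple[str, SequenceRecord]] = [(PLANTED_HOST_TAXON, host)]
    rng = np.random.default_rng(seeds[4])
    if not host_only:
        for d in range(n_decoys):
            taxon = DECOY_TAXA[d % len(DECOY_TAXA)]
            model = CompositionModel.random_skewed(order=3, seed=int(rng.integers(2**31)))
            decoy = generate_genome(
                host_genome_length, model, int(rng.integers(2**31)), genome_id=f"host_{taxon.lower()}"
            )
            hosts.append((taxon, decoy))
            # decoy spacers come from the decoy genome itself: real arrays of
            # other taxa that have nothing to do with this virus
            for sidx in range(2):
                start = int(rng.integers(len(decoy) - 35 + 1))
                spacers.append(
                    SpacerRecord(
                        spacer_id=f"{taxon}_spacer_{sidx + 1}",
                        taxon=taxon,
                        residues=decoy.residues[start : start + 35],
                    )
                )
    background = generate_genome(
        60_000, CompositionModel.uniform(), seeds[5], genome_id="background"
    )

    pollution = _pollution_labels(n_samples)
    study_rng = np.random.default_rng(seeds[6])
    viral_fraction: list[float] = []
    if coupling == "coupled":
        j = 0
        for lab in pollution:
            if lab:
                viral_fraction.append(COUPLED_VIRAL_FRACTIONS[j % len(COUPLED_VIRAL_FRACTIONS)])
                j += 1
            else:
                viral_fraction.append(0.0)
    else:
        lo, hi = np.log(0.001), np.log(0.084)
        for _ in pollution:
            if study_rng.random() < 0.5:
                viral_fraction.append(float(np.exp(study_rng.uniform(lo, hi))))
            else:
                viral_fraction.append(0.0)

    host_fractions: dict[str, list[float]] = {}
    for t_idx, (taxon, _) in enumerate(hosts):
        fr = []
        for fv in viral_fraction:
            if t_idx == 0:
                base = 0.02 + 1.5 * fv + study_rng.normal(0.0, 0.004)
            else:
                base = 0.02 + study_rng.normal(0.0, 0.004)
            fr.append(float(np.clip(base, 0.002, 0.5)))
        host_fractions[taxon] = fr

    samples: list[StudySample] = []
    sample_ids: list[str] = []
    lib_seed_iter = iter(seeds[8:])
    for i in range(n_samples):
        location, depth = divmod(i, 3)
        group = f"S{location + 1}_d{depth + 1}"
        tph = float(study_rng.uniform(300, 2000)) if pollution[i] else None
        for rep in range(n_replicates):
            sample_id = group if n_replicates == 1 else f"{group}_rep{rep + 1}"
            refs = [(virus, viral_fraction[i])] + [
                (genome, host_fractions[taxon][i]) for taxon, genome in hosts
            ]
            pairs, truth = simulate_sample(
                refs,
                n_pairs=n_pairs,
                read_len=read_len,
                error_rate=error_rate,
                duplicate_rate=duplicate_rate,
                seed=next(lib_seed_iter),
                background=background,
                id_prefix=f"{sample_id}",
            )
            samples.append(
                StudySample(
                    sample_id=sample_id,
                    replicate_group=group,
                    tph_ppm=tph,
                    pairs=pairs,
                    truth_pairs=truth["pairs"],
                    truth_duplicates=truth["duplicates"],
                )
            )
        sample_ids.append(group)

    truth = StudyGroundTruth(
        pollution=dict(zip(sample_ids, pollution)),
        viral_fraction=dict(zip(sample_ids, viral_fraction)),
        host_fractions={
            taxon: dict(zip(sample_ids, fr)) for taxon, fr in host_fractions.items()
        },
        spacer_positions=crispr_truth["spacer_positions"],
        crispr_insert_position=crispr_truth["insert_position"],
        dtr_length=dtr_len,
        planted_host_taxon=PLANTED_HOST_TAXON,
        seed=seed,
    )
    return Study(
        virus=virus,
        hosts=hosts,
        background=background,
        spacers=spacers,
        samples=samples,
        ground_truth=truth,
    )


def write_study(study: Study, outdir: str | Path) -> Path:
    """Write a study to disk: FASTQ pairs, manifest, genomes, spacers, truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reads_dir = outdir / "reads"
    reads_dir.mkdir(exist_ok=True)
    manifest_rows = []
    for s in study.samples:
        f1 = reads_dir / f"{s.sample_id}_1.fastq"
        f2 = reads_dir / f"{s.sample_id}_2.fastq"
        write_fastq_pair(s.pairs, f1, f2)
        manifest_rows.append(
            SampleManifestRow(
                sample_id=s.sample_id,
                fastq1=str(f1),
                fastq2=str(f2),
                tph_ppm=s.tph_ppm,
                replicate_group=s.replicate_group,
            )
        )
    write_manifest(manifest_rows, outdir / "manifest.tsv")
    write_fasta([study.virus], outdir / "virus.fa")
    host_records = [
        SequenceRecord(id=g.id, residues=g.residues, description=f"{g.id} taxon={t}")
        for t, g in study.hosts
    ]
    write_fasta(host_records, outdir / "hosts.fa")
    with open(outdir / "spacers.tsv", "w") as out:
        out.write("spacer_id\ttaxon\tsequence\n")
        for sp in study.spacers:
            out.write(f"{sp.spacer_id}\t{sp.taxon}\t{sp.residues}\n")
    gt = study.ground_truth
    with open(outdir / "ground_truth.json", "w") as out:
        json.dump(
            {
                "pollution": gt.pollution,
                "viral_fraction": gt.viral_fraction,
                "host_fractions": gt.host_fractions,
                "spacer_positions": gt.spacer_positions,
                "crispr_insert_position": gt.crispr_insert_position,
                "dtr_length": gt.dtr_length,
                "planted_host_taxon": gt.planted_host_taxon,
                "seed": gt.seed,
            },
            out,
            indent=2,
        )
    return outdir
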