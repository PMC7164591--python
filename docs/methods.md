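# Methods

## Scope and model

`viromarker` answers two questions about a candidate viral contig assembled
from multi-sample shotgun metagenomes: whether its occurrence across
samples co-varies with a binary pollution status, and which candidate taxon
is its most plausible host. The package deliberately re-implements every
inference step as a small, fully specified algorithm rather than wrapping
external aligners or classifiers, so that each step has a testable contract
and deterministic behaviour.

## Direct terminal repeat detection

Assemblers represent a circular viral genome as a linear contig whose two
ends carry one identical copy of the same sequence. The detector computes
all "border" lengths of the contig (prefix = suffix) with the
Knuth–Morris–Pratt prefix function in O(n) and returns the longest border L
with `min_len ≤ L ≤ ⌊n/2⌋`. Matching is exact: assembler-induced end
duplication is exact, and a mismatch tolerance would have no principled
setting. The ⌊n/2⌋ cap prevents a homopolymer (or any highly periodic
contig) from reporting itself as its own repeat. The default
`min_len = 20` makes a chance terminal match on a random contig
vanishingly unlikely (4^-20 per diagonal) while sitting far below the
repeat scale of interest (thousands of bases). Because published contig
lengths may include or exclude the duplicated end, the CLI reports both the
raw and the repeat-trimmed length and does not decide between them.

## Read mapping and abundance

The mapper's contract: a mate maps if (1) it shares at least one exact
seed (default k = 31) with the reference on either strand and (2) its best
ungapped end-to-end placement anchored at such a seed has identity ≥ 0.95.
Ties are broken toward the leftmost reference start, then the forward
strand. N counts as a mismatch; windows containing N are never seeds.
Placements overhanging either reference end are discarded (no circular
wrap-around; DTR duplication already covers the junction).

Implementation: every window of every read is hashed in one vectorized
Horner pass; reference hashes are held in a sorted array and queried by
binary search behind a bitmask prefilter (false positives only), so
unrelated reads cost a few vectorized passes rather than per-read work.
There are no gapped alignments, no mapping qualities and no base-quality
weighting — for presence calling and abundance ratios on substitution-level
divergence these add nothing testable. Ungapped-only extension is a known
limitation: reads spanning indels relative to the reference under-map.

Duplicate removal follows read-pair duplicate-marking semantics: a pair is
a duplicate if both mates' (start, strand) signatures match a previously
seen pair; orphan mates use their own signature; the first occurrence in
input order is kept. Abundance per sample is
`percent_mapped = 100 · dedup_mates / library_size`, where the library size
is the total read count of whatever read set is supplied (the pipeline does
no quality trimming; the denominator is defined by contract, which resolves
the ambiguity between raw and trimmed counts). Breadth is the fraction of
reference positions with depth ≥ 1; each surviving mate contributes each of
its aligned bases once, so overlapping mates double-count depth (stated
simplification). Taxon profiles assign each mate to the candidate genome
with the highest-identity accepted placement; exact ties are left
unassigned rather than split.

## Presence, binarization and co-occurrence

All thresholds are inclusive (≥): presence at `percent_mapped ≥ 0.01 %`,
pollution at `TPH ≥ 125 ppm`, breadth at `≥ 0.75`. The breadth rule is off
for manifest-local runs and on in survey mode (screening public archives,
where percent alone is unreliable across library designs). A missing TPH
value means "below the analyzer's 125 ppm quantification floor" and scores
0 — it is deliberately distinct from a measured 0. Replicate DNA isolations
of one soil sample are averaged after normalization (normalize, then
average). Binary co-occurrence is the phi coefficient computed exactly from
the integer 2×2 contingency table; it equals Pearson r on the 0/1 vectors,
so one estimator covers binary and continuous correlations throughout. The
pipeline reports presence counts at both the library and the soil-sample
level, since the two can differ when replicates disagree. No significance
tests are attached: with a single planned comparison per study there is
nothing to correct for, and n = 12 binary samples cannot support a stable
p-value anyway.

## Host-prediction signals

**CRISPR spacers.** Spacers are scanned ungapped against both strands at
every position, reporting all placements within a Hamming budget (default
3 mismatches). An ungapped scan with a budget replaces a gapped short-read
aligner because spacers are 20–60 bp: an indel-tolerant model would mostly
admit noise, and the budget is explicit and recorded in the output.
Overlapping hits of one spacer are all reported. Minus-strand hits carry
the forward-strand coordinate of the matched window.

**Abundance correlation.** Pearson r between the per-sample viral vector
and each taxon's vector, computed twice: on deduplicated read counts
("raw") and on percent-of-library values ("normalized").

**k-mer composition.** Profiles are counts of all 4^k k-mers (default
k = 4, 256 coordinates, lexicographic order A<C<G<T) on the given strand
only, sliding window of step 1, N-containing windows skipped. Correlation
is Pearson on *relative frequencies*, making a ~68 kb virus comparable with
a much larger host genome. The null shuffles the host genome (uniform
permutation of residues, preserving length and mononucleotide content),
keeps the virus fixed, and reports the mean of 3 shuffles. Counting is
single-strand by default (declared in the output metadata); a
`--canonical` flag counts both strands of every window. Markov-corrected
z-scores (TETRA-style) and dinucleotide relative-abundance signatures are
out of scope.

The merged report declares no winner unless every available signal ranks
the same taxon first, in which case that taxon is flagged `consistent`.
Missing signals render as `n.d.`.

## Synthetic data generator

The generator exists to close the loop: every quantity the pipeline
estimates is planted with known ground truth.

- **Composition**: order-3 Markov chains over {A,C,G,T} with conditional
  distributions drawn from a symmetric Dirichlet(1). Virus and true host
  share one model (the co-residence signature the tetramer signal assumes);
  decoys get independent models; background is uniform.
- **Virus**: 67,826 bp with an 8,697 bp terminal repeat by construction
  (core sampled, prefix copied to the end) — the genome scale the pipeline
  was developed around.
- **CRISPR**: 5 spacers of 35 bp sampled without replacement from the
  virus, interleaved with a fixed repeat unit and inserted at one random
  host position; decoy taxa receive spacers drawn from their own genomes.
- **Libraries**: fragments sampled uniformly per reference in planted
  proportions (multinomial), insert ~ Normal(350, 35) clipped, mates read
  inward from opposite ends, fragment strand random, substitution errors at
  0.005/base (no indels, matching the ungapped mapper), a 5% duplicate
  fraction emitted twice with fresh ids, and qualities constant (the
  pipeline never reads them).
- **Study shape**: 12 samples = 4 locations × 3 depths; the deep sample of
  every location except the third (the control) is polluted. Polluted
  samples receive TPH ~ Uniform(300, 2000) ppm; clean samples have missing
  TPH (below quantification). In *coupled* mode the three polluted samples
  carry the virus at 8.4 %, 0.8 % and 0.1 % of reads — the strong/weak/
  trace pattern the thresholds were standardized on — and the true host's
  fraction is `0.02 + 1.5·f_virus + Normal(0, 0.004)` (clipped at 0.002);
  decoys get the same base level without the coupling term. Default 2,500
  pairs per sample and one library per soil sample (a `n_replicates` knob
  generates replicate isolations); 40 kb host genome segments stand in for
  full host genomes. These scales keep a full 12-sample study at a few
  seconds while leaving every estimated quantity (trace presence at 0.1 %,
  correlation contrasts, spacer and DTR recovery) well-identified.
- **Independent (null) mode** breaks the virus–pollution coupling. The
  presence pattern is drawn i.i.d. Bernoulli(1/2) per sample — the
  maximum-entropy null over presence patterns — with fractions log-uniform
  on [0.001, 0.084]; the pollution design stays fixed. With 12 binary
  samples the phi distribution is coarse: exact enumeration shows
  P(|φ| ≥ 0.5) ≈ 0.08 under this null (and ≈ 0.13 if instead the three
  coupled fractions were merely shuffled, which is why that design was not
  used). The "null studies rarely reach |φ| ≥ 0.5" property is therefore
  expected to hold in ~92 % of runs, not almost surely.

What the generator does *not* emulate: quality-score structure, GC/coverage
bias, indels, chimeras, strain-level variation, and real inter-genome
homology. Passing tests therefore demonstrate correctness of the inference
chain under its own model assumptions, not robustness to real-data
artefacts such as conserved regions shared between virus and non-host
genomes.

## Numerical and design choices

- Thresholds inclusive (≥) everywhere; the convention is echoed in report
  headers.
- Pearson is used for all correlations (binary, abundance, k-mer) so the
  study-level statistics come from one estimator; phi is computed from the
  integer contingency formula for bit-exactness on table-derived flags.
- Degenerate inputs (constant vectors, flat k-mer profiles) raise a typed
  error and are rendered as missing rather than emitting a number.
- Mapper ties: identity, then leftmost start, then forward strand —
  deterministic under read-order permutation.
- All generators and analyses are deterministic per (parameters, seed);
  child seeds derive from one integer stream per study.
- The `cli_pipeline` stage is a thin click CLI (`simulate`, `dtr`,
  `abundance`, `spacers`, `kmer-host`, `cooccur`, `host-predict`,
  `run-all`) over the library; `run-all` echoes its config such that
  re-running from the echo is bit-identical.

## Known limitations

- Ungapped mapping and substitution-only simulation are mutually
  consistent but under-map indel-divergent reads on real data.
- Best-hit taxon profiling has no concept of shared/homologous regions
  between candidate genomes beyond the exact-tie rule.
- The k-mer signal is computed on whatever host sequence is supplied;
  for draft genomes composed of short contigs the single-strand,
  whole-sequence profile is noisier than a per-replicon profile.
- Breadth-based presence (survey mode) assumes roughly uniform coverage;
  libraries with strong coverage bias can fall below the 75 % cut despite
  genuine presence.
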