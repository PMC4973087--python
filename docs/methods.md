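# Methods

This note documents the models, conventions and design choices behind
`middrad`, in the order data flows through the toolkit.

## Restriction-site model

An enzyme is a recognition motif over the 15-letter IUPAC DNA alphabet
plus two cut offsets (top and bottom strand, in bases from the motif
start). The built-in table carries REBASE-standard offsets for the seven
enzymes the toolkit targets (AvaII `G^GWCC` 1/4, MspI `C^CGG` 1/3, EcoRI
`G^AATTC` 1/5, PstI `CTGCA^G` 5/1, SbfI `CC^TGCAGG` 2/6, MluCI `^AATT`
0/4, NlaIII `CATG^` 4/0); users can override or extend it with a TSV of
the same shape. Cut offsets are fixed biochemical facts, not tunables.

Site scanning expands the motif to its concrete ACGT strings and matches
with an overlap-tolerant regex. Minus-strand scanning is only performed
for enzymes whose expansion set is *not* closed under reverse complement
(`self_rc`); for palindromes — including the degenerate-palindromic AvaII,
where rc(GGACC) = GGTCC — both orientations are the same physical site.
Windows containing any non-ACGT character never match: this is the
conservative choice, since inventing sites inside assembly gaps (N runs)
would inflate fragment counts.

## Digestion conventions

- Coordinates are 0-based, intervals half-open, throughout.
- Fragment boundaries are **top-strand** cut coordinates; the sticky-end
  overhang (≤ 4 bp per end for these enzymes) is ignored for length.
  The bottom-strand coordinate of each bounding cut is nevertheless kept
  on the `Fragment`, because the read simulator needs the physical strand
  extents (see below).
- Coincident cut coordinates from the two enzymes are deduplicated (the
  alphabetically first enzyme labels the cut), so zero-length fragments
  cannot arise.
- Size windows are inclusive on both ends ("between 400–700 bp" reads
  inclusively). Histograms use half-open 100-bp bins over [0, 1500) plus
  one overflow bin.
- Counting defaults to **AB fragments only** — one end cut by each
  enzyme — because only those receive both adapters and amplify. AA, BB
  and terminal counts are computed and reportable; which classes a
  published total includes can be genuinely ambiguous, so both readings
  are exposed.
- Genome size for density metrics defaults to total assembly length
  (including Ns) and can be overridden with a cited C-value, which is
  what practitioners usually quote.

## Tag-yield regression and summary metrics

The genome-size model is unweighted ordinary least squares of the AB
count (total or in-window) on genome size in Mb, via
`scipy.stats.linregress`; R² is reported to 4 decimals, predictions are
floored at 0. No transform is applied — across tens of plant genomes the
relation is adequately linear, and an untransformed fit keeps the slope
interpretable as "fragments per Mb".

Summary metrics round half-away-from-zero to 2 decimals to match printed
tables. Mean tag depth divides the **clean read count** by the tag count;
for paired data the read-1 count is the conventional numerator. The
expected/observed percentage is the plain ratio × 100. For paired-end
libraries where both fragment ends are sequenced and genotyped, the
genome-fraction (simplification) calculation uses 2 × 140 = 280 bp of
sampled sequence per tag.

Known discrepancy: one published rice expected/observed figure (86.54 %)
is not reproducible from the tag counts printed beside it
(60,925 / 66,547 = 91.55 %); the toolkit implements the plain ratio and
leaves that figure aside rather than guessing an undocumented convention.

## Barcode and adapter design

The barcode generator reproduces a design *system*, not a specific oligo
batch: sets of 20·n barcodes of 4–8 bp satisfying

1. **prefix-freeness** — with variable lengths the downstream restriction
   remnant, not a fixed column, delimits the barcode, so no barcode may
   be a prefix of another;
2. **pairwise Levenshtein distance ≥ 2** (single-error detection; the
   distance is configurable) — computed with edlib;
3. **no site reconstitution** — the last `cut_offset_top` bases of a
   barcode must not match the start of the enzyme-A motif, otherwise
   barcode + remnant would rebuild a cleavable site at the ligation
   junction (for AvaII: no terminal G, since G + GWCC = GGWCC);
4. **length balance** — lengths are dealt round-robin across the allowed
   range, so each class holds an equal (±1) share; 20 barcodes over
   lengths 4–8 give exactly 4 per length. The exact staggering of any
   particular published set is unknown; balance across the full range is
   this package's choice, stated here once.

Generation is greedy rejection sampling from a seeded PRNG with a bounded
attempt budget (200,000 candidates by default); for 20–60 barcodes it
succeeds in well under a second for every seed tried.

Adapters follow the shortened-P1 length contract
`len(P1) = 20 + len(barcode)` (25 bp at the canonical 5-bp barcode). The
20 fixed stub bases are an Illumina-compatible placeholder — only the
length contract and the 3' overhang (reverse complement of the enzyme's
sticky end; degenerate positions stand for mixed-base oligos) are
normative. Blunt cutters are rejected since the ligation chemistry needs
sticky ends.

Sample sheets assign samples round-robin to (barcode, pool-index) pairs:
40 samples over 20 barcodes × 2 pools use every barcode exactly twice,
once per pool.

## Read simulation

The simulator generates what the protocol sequences: for every AB
fragment inside the window, for every sample, k read pairs with
k ~ NegativeBinomial(mean, dispersion). The NB choice (over Poisson) is
deliberate: real pools are over-dispersed by ligation and PCR efficiency
differences, and the coefficient-of-variation analyses need that
imbalance. `dispersion = inf` degenerates to exact fixed depth, which the
round-trip tests use so that every stack clears the minimum-depth
threshold deterministically.

Read anatomy: R1 = barcode + enzyme-A remnant + insert, R2 = enzyme-B
remnant + insert from the other end. Reads are extracted from the
*sticky* fragment — the top strand runs between the two top-strand cuts,
the bottom strand between the two bottom-strand cuts, and reading from
the right end means reverse-complementing the bottom-strand extent. This
is what makes the full remnant (e.g. GWCC) appear at the read start
regardless of which side of the genomic interval the A-end cut falls on.

When the template is shorter than the read and read-through is enabled,
the read continues into the reverse complement of the opposite adapter
(degenerate adapter positions concretized), then into poly-A padding —
the signature that the adapter-fraction QC detects. Errors are i.i.d.
substitutions only; indels are out of scope since the downstream
clustering is Hamming-based. Qualities are constant Q37 with an optional
3'-taper. PCR duplicates are not modelled separately from depth (the
protocol has no UMIs).

Planted variants (for SNP-recovery tests) are applied to the extracted
fragment sequence, not to the genome before digestion, so a variant can
never create or destroy a cut site; plant variants away from remnant
positions. Both A-left and A-right fragment orientations occur naturally
in a digest, exercising both read-strand code paths.

## Demultiplexing and QC

Candidate barcodes are compared longest-first over their own length at
the read start; a candidate must also show the enzyme-A remnant within
tolerance immediately downstream (the remnant anchor is what resolves
length ambiguity once mismatches are allowed — exact matches are already
unambiguous by prefix-freeness). Candidates are ranked by (barcode
mismatches, remnant mismatches); a tie at the best rank means the read is
unassigned, never guessed. Default tolerance is 1, consistent with
distance-2 sets. Pool indexes are matched exactly, as sequencers
demultiplex them upstream.

The quality filter discards a read if any 15-base sliding window has mean
Phred < 10 (reads shorter than one window are judged on their whole-read
mean). The adapter search follows the usual 3'-adapter semantics: a
prefix of the adapter may begin at any position (everything downstream
would be trimmed), with ≥ 10 bases of overlap and ≤ 10 % mismatches; the
10-base minimum overlap is a documented default, and tests that demand
exact agreement with simulated truth use 15 to push the false-positive
rate to negligible.

CV uses the sample (n−1) standard deviation over the mean; "sd/mean"
without a stated ddof is ambiguous, so the convention is fixed here and
reported to 4 decimals.

## Tag clustering

An explicit simplification of the ustacks/cstacks/sstacks approach,
self-contained so it can be oracle-tested:

- identical truncated reads (140 bp default) form exact stacks; stacks
  with depth ≥ m (default 10) are primaries;
- primary stacks with depth > mean + 3·sd of primary depths are flagged
  repetitive and excluded — a depth-outlier stand-in for the removal /
  deleveraging algorithms, documented as such and *not* claimed
  equivalent (it needs a reasonable number of primaries to have power;
  with few stacks an outlier can mask itself);
- primaries merge by single linkage at ≤ M Hamming mismatches (deepest
  seeds first), then sub-threshold stacks attach to the best group
  (fewest mismatches, ties to the deeper group, then lexicographic
  consensus). Consensus is depth-weighted column majority with
  lexicographic tie-break;
- the catalog is greedy single linkage over tag consensuses at ≤ n
  mismatches (default 5), in deterministic (sample, consensus) order;
- genotyping assigns each tag to its unique best locus within n
  mismatches and records its bases at the locus's variant columns;
  multi-allele columns are IUPAC-coded; absent samples get `N`.

Everything is ordered deterministically (sample name, then lexicographic
consensus), so outputs are byte-stable. Conservation holds per sample:
Σ tag depths + dropped-short + unmerged-below-m + repetitive-excluded =
input reads.

Phylip export is sequential with names padded to 10 characters; at least
3 samples are required for an informative unrooted tree (warned below).
A fixed-within / variable-among species SNP screen is exposed with
explicit parameters rather than guessed thresholds. Gapped alignment,
likelihood SNP models, population-genetic statistics and tree inference
are out of scope — the Phylip file is the hand-off point.

## What the synthetic data does and does not show

The synthetic genome is i.i.d. bases at a target GC with optional
repeat-unit copies pasted into unit-aligned blocks. It exercises site
scanning, fragment statistics, repeat-stack exclusion and the full
pipeline round trip, but it lacks real genomes' long-range composition
structure, transposon families, and methylation; absolute fragment
yields on real genomes can differ substantially from i.i.d. expectations
(real rice/maize screens also depend on assembly version). Passing
round-trip tests therefore demonstrates pipeline correctness and
internal consistency, not field performance on any particular species.

## Problem sizes and numerical choices

Default test and reproduction runs use a 1-Mb two-contig genome, 3
samples at fixed depth 20 (≈ 14,000 read pairs), a 40-sample balance
simulation on a 150-kb genome, and 1,000 random 0.2–3 kb sequences for
the digestion oracle — sizes chosen so the whole suite runs in seconds on
one core while every code path (both fragment orientations, variable
barcode lengths, repeat exclusion, planted SNPs) is exercised. Reported
percentages and ratios round half-away-from-zero (2 decimals), R² and
correlation coefficients to 4; all PRNGs are numpy `default_rng` or
`random.Random` seeded explicitly, and a single CLI/API seed propagates
to every stochastic component.
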