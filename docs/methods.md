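# Methods

## The detection model

A diversity-generating retroelement leaves two diagnostic sequence features:
a near-identical direct repeat pair near a reverse-transcriptase (RT) gene,
and a strongly one-sided mismatch pattern — the mismatched columns are
adenine in exactly one of the two copies, because mutagenic retrohoming
copies the template repeat (TR) through an error-prone cDNA that
mis-incorporates opposite template adenines before replacing the variable
repeat (VR).

`dgrscan` models the repeat pair gaplessly: the TR and VR are treated as two
equal-length copies aligned column by column, with no indels. Published phage
cassette alignments are gapless at this scale, and a gapless model makes
every downstream count (mismatch columns, adenine ownership, codon context)
exact rather than alignment-dependent. Inputs whose repeats genuinely differ
in length are reported as errors, never silently re-aligned.

### Repeat discovery

Within `rt_window` (default 20 kb) of each RT ORF, candidate pairs are found
by shared exact k-mers (`seed_k` = 11) and extended greedily in both
directions. Two-pass seeding falls back to 7-mers when 11-mer seeding finds
nothing: by pigeonhole, even 14 mismatches spread over a 117 bp repeat leave
a clean stretch of at least 7 bp, so the fallback guarantees a seed for any
repeat pair at the mismatch densities the caller accepts.

Extension stops when the trailing 12 columns accumulate 9 or more
mismatches (random flanking sequence mismatches ~75% of columns and halts
extension almost immediately, while a true repeat interior at ≤ 25% mismatch
essentially never saturates the window), when the cumulative mismatch
fraction exceeds `max_mismatch_fraction` (0.25), at an N, or when the copies
would collide. The raw extension is then trimmed on each side to the
maximal-scoring extent under match = +1, mismatch = −3. This trim defines
the boundary convention: termini are always matching columns, boundaries are
deterministic, and a terminal segment survives only if its matches outnumber
three times its mismatches. Pairs shorter than `min_repeat_len` (40 bp),
separated by more than `max_copy_separation` (5 kb), or above the mismatch
fraction cap are discarded; seeds landing inside an already-extended
diagonal interval are skipped, so one duplication yields one maximal pair.

### Orientation and calling

The copy owning more adenines at mismatched columns is the TR. Adenine
specificity is strand-dependent (a template adenine reads as thymine on the
opposite strand), so both polarities of the pair are evaluated and the one
with the stronger adenine ownership wins; coordinates stay in region space.
Ties fall back to CDS overlap (the copy inside an annotated ORF is the VR,
since retrohoming targets coding sequence); if that is also uninformative
the pair is reported with `copy1 = TR` and an ambiguity flag rather than a
silent guess.

A cassette is called when the TR contains at least `A_min` = 10 adenines and
at least `S_min` = 7 mismatch columns are TR-adenines. The threshold is ≥ 7
("minimum 7"), and both knobs are exposed. The adenine-bias p-value is the
one-sided binomial tail P(X ≥ a | n = total mismatches, p = TR adenine
fraction) — a composition-aware descriptive statistic, not multiplicity
corrected, since it annotates single cassette rows. Within one RT locus,
retained pairs are ranked by proximity to the RT ORF; rank 1 mirrors the
convention of reporting the first TR/VR pair.

The VR's residue interval in its target ORF is the 1-based span of the
overlap between the VR and the ORF's codons, clamped to the translated
length (a VR that runs over the stop codon reports its last translated
residue).

### RT anchors

RT loci come either from HMMER domain-table text (PF00078 rows mapped onto
region ORFs by `<region>_<n>` naming) or from a built-in fallback motif scan
flagging ORFs of ≥ 200 aa whose translation matches `[YFLIVM].DD`, the
RT catalytic core. The motif scan is a coarse anchor-finder, not a substitute
for a profile search; it exists so the scanner runs on plain annotated
sequence.

## Activity, lifestyle, abundance

Coverage is computed from SAM text: depth increments over M/=/X CIGAR spans
(deletions consume reference but add no depth); unmapped, secondary and
supplementary records are excluded; the optional identity filter computes
(aligned − NM)/aligned from the NM tag and is applied at 0.97 by default.
A region is **active** iff mean fold coverage > 10 — strictly, so exactly
10.0× is inactive. Reads are not deduplicated (upstream read QC is out of
scope here).

Lifestyle calls collapse per-replicate temperate probabilities: temperate if
mean − sd > 0.5, lytic if (1 − mean) − sd > 0.5, otherwise NA. The standard
deviation is the sample (n−1) estimate by default, exposed as an option,
with the boundary strict. Enrichment of DGR carriage among temperate phages
is a Pearson goodness-of-fit chi-square against expectations proportional to
the database's background composition, df = classes − 1, with a warning when
an expected cell drops below 1.

Fractional abundance is recruited primary alignments at the identity
threshold divided by total reads — the simplest transparent definition —
with an optional per-kilobase normalization for cross-reference comparisons.
The global-virion estimate is the product prevalence × virions-per-carrier ×
population with all three inputs explicit; no default parameter values are
baked in because any such estimate is only as good as its inputs.

## The simulator

`plant_cassette` generates the canonical cassette anatomy: random
background, a target ORF with the VR spliced in-frame at its 3′ end, the TR
in intergenic sequence, and an RT ORF carrying a QGYMDD catalytic core. The
VR is produced by `retrohome`: each TR adenine is independently replaced
with probability `mutation_prob` by a uniform draw from the three other
bases, so `mutation_prob` equals the realized per-adenine mismatch
probability exactly (the biological process can also re-incorporate A; this
parameterization trades that nuance for exact test arithmetic).

Planting is designed so truth coordinates are exact detection truth:

- the six columns flanking each repeat copy are forced to disagree between
  the two loci ("clean flanks"), editing only intergenic bases;
- mismatch placements are rejection-sampled so no two are adjacent and every
  terminal prefix of the repeat out-scores the trim penalty, so
  maximal-scoring trimming recovers the planted boundary exactly;
- backgrounds are rejection-sampled against any duplicate 25-mer not
  explained by the planted pair;
- filler/target codons exclude stops and aspartate, so no ORF other than the
  planted RT can match the RT motif and anchor a second, duplicate call.

Defaults: 10 kb genome, 117 bp TR with 30 adenines, mutation probability
0.5, 100 bp error-free reads. The 10 kb default keeps hundred-replicate
recovery experiments cheap while leaving realistic spacing between cassette
parts. `synth_reads` draws `round(fold × L / read_len)` uniform reads with
independent substitution errors; `naive_map` places a read at the unique
exact match of its leading 31-mer (forward or reverse complement), emitting
full-length-M CIGARs with NM by direct comparison. It is deliberately simple
test plumbing — unique-seed placement, no indels, no quality model — not a
production mapper.

What the simulator does *not* emulate: indels and structural variation,
quality-score error profiles, non-uniform coverage biases, multi-copy or
cascaded VR arrangements, and insertion-site preference. Passing tests
therefore demonstrate correctness of the detection and coverage arithmetic
under the clean-cassette model, not robustness to real-world alignment noise.

## Synthetic reference stand-ins

`synthetic_refs` builds deterministic stand-ins reproducing the documented
anatomy of the two exemplar cassettes — the Hankyphage-style prophage
(42,831 bp, 45 CDS, 117 bp repeats mismatched at 14 TR-adenine positions,
VR at residues 2188–2225 of a 2,225-residue C-type-lectin-fold target ORF,
with the repeat's final three bases spanning the stop codon) and a
BPP-1-style segment (134 bp VR inside the mtd tail-fiber gene). All
non-cassette sequence is random under fixed internal seeds. These objects
are clearly labelled synthetic: they validate that the toolkit's readers,
scanner and reporters reproduce every printed anatomical number on a genome
of the right shape, not that they reproduce the published sequences.

## Numerical and interface conventions

- Coordinates are 0-based half-open internally; every human-facing report is
  1-based inclusive. The conversion is a bijection and is property-tested.
- Ambiguous bases are kept as N; columns containing N never count as
  matches, mismatches, or adenines — conservative in every statistic.
- Sequence space is the exact big integer 4^n over n variable nucleotide
  positions; no floating point is involved, and the order-of-magnitude
  comparison against 10^12 is done on exact integers.
- Reports are byte-stable for a fixed input order; simulator outputs are
  bit-for-bit reproducible from (params, seed) with no global RNG state.

## Known limitations

- Gapless repeats only: indel-divergent TR/VR pairs and inverted-repeat DGRs
  are out of scope.
- The scanner reports per-RT; a repeat pair within reach of two RT ORFs
  would be reported once per anchor.
- The DiGRef search window and minimum repeat length are not published;
  `rt_window` = 20 kb and `min_repeat_len` = 40 bp are this package's
  defaults and are configurable.
- The chi-square enrichment and global-virion calculators accept any counts;
  the published P = 0.0012 and 3.3 × 10^17 figures depended on inputs that
  are not printed, so they are parameterized rather than reproduced.
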