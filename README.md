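# dgrscan

Detection and analysis of **diversity-generating retroelements (DGRs)** in
phage and prophage genomes.

A DGR is a genetic cassette — a reverse transcriptase (RT), a template repeat
(TR), and a variable repeat (VR) embedded in a target gene — that rewrites the
VR through error-prone reverse transcription of the TR ("mutagenic
retrohoming"). The copying errors land specifically at TR **adenine**
positions, so a genuine DGR leaves a recognizable footprint: two near-identical
repeats whose mismatched columns are adenines in one copy (the template) and
anything else in the other (the variable copy). Phage-encoded DGRs diversify
host-interaction proteins such as tail fibers and C-type lectin folds, and the
activity of the prophages that carry them can be read out from virome read
recruitment.

`dgrscan` is a library plus a command-line tool for:

- **Cassette detection** — k-mer seeded, gaplessly extended direct-repeat
  discovery near RT loci; orientation of the two copies into TR/VR by adenine
  ownership at mismatch columns; calling with DiGRef-style thresholds
  (≥ `A_min` = 10 adenines in the TR, ≥ `S_min` = 7 adenine mismatches) and an
  adenine-bias binomial p-value.
- **Prophage activity** — per-base coverage from SAM alignments with a 97%
  nucleotide-identity filter; a region is "active" (virion-producing) when
  mean fold coverage strictly exceeds 10×.
- **Lifestyle statistics** — confident temperate/lytic calls when the mean
  replicate score minus its standard deviation clears 0.5, and a chi-square
  test for DGR enrichment among temperate phages.
- **Diversification analysis** — TR invariance, the census of variable VR
  positions across lysogens, adenine specificity, asparagine-codon context,
  and the exact sequence space `4^n`.
- **Abundance** — identity-filtered fractional abundance of a phage in a read
  set, and a parameterized global-virion estimate.
- **Simulation** — a mutagenic-retrohoming simulator that plants cassettes
  with known ground truth and generates virome-like reads, used throughout the
  test suite. Deterministic synthetic stand-ins reproducing the published
  anatomy of the Hankyphage and BPP-1 cassettes are built at run time
  (`dgrscan.synthetic_refs`; these are labelled synthetic and are not the
  published sequences).

## Worked example

Plant a DGR cassette in a synthetic 10 kb genome and scan it:

```sh
dgrscan simulate --preset cassette --seed 1 --out fixture/
dgrscan scan --genbank fixture/cassette.gbk --out report.tsv
```

The scan log line (stderr) records every resolved threshold:

```
# params: A_min=10 S_min=7 ... n_cassettes=1 subcommand=scan ...
```

and `report.tsv` contains one cassette row (coordinates 1-based inclusive):

```
region_id      rank  rt_start  rt_end  ...  tr_start  tr_end  vr_start  vr_end  repeat_length  tr_adenine_count  adenine_mismatches  total_mismatches  adenine_bias_fraction  ...
planted_seed1  1     1371      2273    ...  1154      1270    884       1000    117            30                9                   9                 1                      ...
```

Read it as: near the RT ORF (1371–2273) the scanner found a 117 bp direct
repeat pair; the copy at 1154–1270 owns the adenines at all 9 mismatched
columns, so it is the template repeat, and the copy at 884–1000 — inside the
target ORF — is the variable repeat. All 9 of 9 mismatches are at TR-adenines
(`adenine_bias_fraction` = 1), the unmistakable retrohoming signature.

Coverage-based activity of the same region from simulated virome reads:

```sh
dgrscan activity --sam reads.sam --region-id planted_seed1
region          mean_fold  breadth  n_reads  verdict
planted_seed1   11.9400    0.9998   1194     active
```

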