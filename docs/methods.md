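# Methods

## Observation model

A sequencing library from the enrichment + APOBEC-deamination assay is a
set of single-stranded molecules. Each fragment derives from one strand of
the denatured duplex — the *original top* (OT) or *original bottom* (OB)
strand — and only that strand's cytosines pass through the chemistry:
unmodified C and 5mC deaminate and are read as T, glucosyl-protected 5hmC
stays C, and 5fC/5caC (if modelled) also resist deamination. Against the
forward reference this appears as C→T substitutions for OT fragments and
G→A for OB fragments. Calling therefore enumerates every reference C (OT)
or G (OB) covered by either mate and classifies the read base:

- `converted` — read T (OT) / A (OB): the cytosine was C or 5mC;
- `unconverted` — read C (OT) / G (OB): a 5hmC signal;
- `ambiguous` — any other base, base quality < Q20, or mate disagreement.

Ambiguous calls never count toward any filter or tally. A position covered
by both mates produces exactly one call; the fragment (pair) is the unit of
every downstream decision. Cytosine context (CpG/CHG/CHH) comes from the
reference on the reading strand, never from the read; positions whose
deciding window holds an N or runs off the contig get no context and are
excluded. Alignment is modelled as ungapped: SAM records whose CIGAR is not
a single match run are skipped with a logged count, which keeps the
observation model exact at the cost of ignoring indel-containing reads.

## Filters

1. **Conversion filter.** Fragments with more than 3 (default,
   configurable) unconverted cytosines in non-CpG context are discarded:
   non-CpG cytosines are essentially never hydroxymethylated, so several
   unconverted ones indicate the molecule escaped deamination. The rule is
   strict-greater (exactly 3 is kept) and applies to the whole pair —
   deamination failure is molecule-level.
2. **Presence filter** (`ebs` mode only). Fragments with no unconverted
   CpG are discarded. In an enrichment library every genuine pull-down
   fragment should carry at least one 5hmC; signal-free pairs are
   carry-over. Only CpG-context signals satisfy the rule, since non-CpG
   unconverted cytosines are treated as conversion noise handled by
   filter 1. Fragments whose only CpG evidence is ambiguous are discarded.

Stage order is: call → conversion filter → spike partition → coordinate
dedup → presence filter → quantify. Dedup before the presence filter keeps
duplicated signal-free pairs from inflating the reported no-5hmC fraction.
Spike reads are split off *before* dedup because spike oligos are
fixed-length molecules sharing identical coordinates — coordinate dedup
would collapse legitimate copies — and because QC should see every spike
molecule. The spike QC report is produced both without (primary) and with
the conversion filter applied, since either convention is defensible for
whole-molecule non-conversion accounting.

Deduplication keys on (contig, fragment start, fragment end, conversion
strand), mirroring directional-library semantics; the survivor is the
highest mean base quality, ties broken by input order.

## Quantification

Per-CpG tallies record `hmc_count` (unconverted CpG calls) and `coverage`
(informative calls) per site; reverse-strand calls fold onto the dyad's
forward C coordinate when strand-merged (the default — 5hmC at a CpG dyad
is interpreted dyad-wise), while the cytosine report keeps strands separate
by format convention (1-based positions; bedGraph is 0-based half-open).

Region signal comes in two deliberately contrasted forms:

- **RPKM** = count / (length/10³) / (library/10⁶) on fragment counts, with
  each fragment assigned to the single region containing its midpoint (so
  totals conserve);
- **CpG-normalized signal** = ((5hmC in region / total 5hmC) × 10⁶) /
  (CpG sites in region). In an enrichment library coverage tracks CpG
  density, so RPKM inflates CpG-dense regions; the normalized signal is
  invariant to density at fixed per-CpG signal rate. The two-region fixture
  in the tests (equal per-CpG rate, 10× density difference) shows equal
  normalized signal and a 10× RPKM gap.

High-confidence sites are dyads with ≥3 signals (default). Replicate
agreement is Pearson on raw (unlogged) per-bin RPKM over a fixed
non-overlapping 10 kb tiling; a step-size option provides sliding windows.
Metagene profiles use a scale-regions layout — 3 kb flanks (default) in 30
fixed bins each, bodies rescaled to 100 bins — in two modes: mean per-base
fragment coverage, or 5hmC count per CpG site per bin (missing where a bin
holds no CpG); minus-strand rows are reversed to read 5'→3'. Expression
correlation is Pearson between gene-body signal and expression after
dropping genes with zero on either side.

## The simulator

The generator emulates the chemistry end to end under one seed, with named
sub-streams (genome, placement, fragmentation, pull-down, conversion,
error, duplication, spike) so stages can vary independently. Defaults are
the study conditions of the assay:

| parameter | default | note |
| --- | --- | --- |
| fragment length | N(200, 50) bp, min 50 | sonication-scale inserts |
| read length | 150 bp paired | 150PE layout; fragments > 300 bp have an uncovered middle |
| conversion P(C), P(5mC), P(5hmC) | 0.994, 0.989, 0.008 | measured assay chemistry |
| capture / carry-over | 0.95 / 0.01 | pull-down of ≥1-5hmC vs signal-free fragments |
| sequencing error | 0.001/base | flat model, applied after conversion |
| duplicate rate | 0.02 | exact re-reads, removed by dedup |
| genome | 200 kb, GC 0.45, 20×5 kb genes, 10×1 kb CpG islands | desk-scale analog of a genomic slice |
| 5hmC per CpG cytosine | 0.10 gene body / 0.05 island / 0.01 intergenic | gene-body and promoter enrichment, intergenic depletion |
| 5mC per CpG cytosine | 0.60 body & intergenic / 0.10 island | hypomethylated islands |

Dyad strands draw independently (hemi-modification allowed) with a
`symmetric_dyads` switch; 5fC/5caC is supported (never deaminated) but
defaults to 0. The chemistry acts on the fragment's original strand only,
matching single-strand deamination after denaturation. Reads are emitted
pre-aligned (true coordinates, `ZS` strand tag) so no aligner is needed;
FASTQ is also written for users who want to exercise one.

The spike-in design is a synthetic stand-in for the assay's control oligo
pair (the real sequences are not published): two 200 bp duplexes identical
except for four A↔T swaps, which survive both C/T and G/A
conversion-collapse, so deamination can never break spike assignment. The
5hmC duplex carries 5hmC/5mC at alternating CpGs (dyad-symmetric); the
control is fully unmodified.

What the simulator does *not* emulate: PCR amplification bias, adapter
content, realistic quality-score profiles, alignment/mapping error,
indels, neighbour effects of 5hmC on adjacent-cytosine deamination, and
correlated (regional) modification structure beyond the three region
classes. Passing tests therefore demonstrate correctness of the in-silico
processing under this generative model, not robustness to artefacts of
real libraries (mapping bias, chimeras, library-prep chemistry drift).

## Verification strategy and problem sizes

- Spike chemistry recovery simulates 100,000 spike molecules and requires
  each per-class conversion count to sit in the 95% binomial CI of its
  configured probability (sequencing error disabled so the CI is exact).
- The noiseless limit — conversion (1, 1, 0), no error, capture 1,
  carry-over 0 — must reproduce the truth 5hmC set restricted to covered
  dyads *exactly*; the expected set is derived from truth + read geometry,
  independent of the calling path.
- Both filters are checked fragment-by-fragment against a brute-force
  pure-string re-derivation from the raw reads (1,000 fragments).
- The no-5hmC fraction at 50,000 molecules is compared with a closed-form
  expectation computed from the truth-annotated candidates: per fragment,
  P(retained) is capture or carry-over, and P(no signal) is the product of
  per-covered-CpG conversion probabilities; tolerance is 5 binomial
  standard errors.
- Replicate correlation uses two 20,000-fragment libraries drawn from one
  truth over twenty 10 kb bins (property threshold 0.9; identical input
  must give exactly 1.0, enforced by an explicit equal-vector branch since
  floating-point normalization need not return 1 bit-exactly).
- Metagene contrast places 5hmC only in gene bodies and requires the
  body-bin mean to exceed every flank bin.

These sizes were chosen so each check is statistically decisive at desk
scale while the whole suite stays fast; they are not estimates of real
library depth. Published real-data figures for this assay family
(replicate correlation ≈0.98, expression correlation R = 0.43, site-overlap
percentages, mapping ratios) require the deposited sequencing data and are
deliberately out of scope here.

## Numerical and edge-case choices

- Coordinates are 0-based half-open internally; 1-based only in the
  cytosine report.
- CpG context is decided by the +1 base alone, so it survives an N at +2;
  CHG/CHH require both bases.
- Empty inputs: an empty call set is valid (kept by the conversion filter,
  dropped by the presence filter); an empty filter report carries
  NaN insert-size means; zero spike reads, zero total 5hmC, zero-length
  regions, and <3 genes after exclusion are errors.
- Zero-variance replicate vectors yield NaN correlation entries rather
  than an error.
- Mid-length fragments (150–300 bp) get partially overlapping mates; the
  overlap region is double-read and resolved to one call.
- `infer_conversion_strand` is a majority vote over C→T vs G→A evidence;
  an input `ZS` tag wins over a contradicting majority (logged), and a tie
  without a tag raises.
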