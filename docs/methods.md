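# Methods

## Domain model and detection

The bHLH domain is modeled as four contiguous regions on a 1-based domain
coordinate: basic (positions 1–17), helix 1 (18–32), an elastic loop
(length 5–15, canonical 6), and helix 2 (the final 22 positions). A
canonical domain therefore spans 54 + loop residues (60 at the modal loop).
Region sizes are configurable through `RegionTemplate`; the defaults encode
the usual descriptions of the domain (a ~17-residue basic region, ~60
residues overall) and are not fitted to data.

Detection is consensus matching, not profile-HMM scoring. A seed alignment
is collapsed per column to its modal non-gap residue; the denominator for
the *scanning* consensus is gap-excluded (the modal residue among observed
characters), ties break alphabetically, and all-gap columns keep a sentinel
with fraction 0. Columns whose fraction reaches the threshold (default
0.5) are the *consensus positions*; only they are scored. Scanning a query
protein enumerates every start offset and every loop length in range; a
placement's score is the count of consensus positions whose query residue
differs from the consensus residue ('X' and gaps never match). The loop is
compared only over the first `min(consensus loop, candidate loop)` residues
— surplus residues on either side are uncounted, which is what makes the
loop elastic without alignment machinery. The minimizing placement wins;
ties prefer the loop closest to six residues, then the smaller start, then
the smaller loop. A candidate is accepted when its total mismatch count is
at most the budget (default 12, applied to the whole domain; per-region
counts are always reported so users can impose their own per-region caps).

The scan is vectorized with numpy (per loop length, all starts are scored
with one comparison over the consensus-position offsets); the test suite
holds an independent pure-Python exhaustive scorer and asserts equality of
the chosen placement on synthetic proteins.

The consensus itself is an input artifact, not shipped knowledge: any
aligned domain FASTA can seed the scanner. The packaged toy seed
(8 rows × 60 columns) collapses to a canonical domain whose four residue-rule
positions and entire HLH portion are conserved (47 consensus positions)
while the 13 non-rule basic-region columns are deliberately diverse — the
basic region's *composition* varies across real family members, and leaving
those columns below threshold keeps composition changes cost-free in the
mismatch count.

## Binding classification

Classification is a fixed decision tree over four 1-based rule positions
(9, 13, 16, 17) and the basic-residue count of positions 1–17. The basic
set is {Arg, Lys, His}; His is included because position 9 of the G-box
rule itself treats His as functional. The binder bar is "at least five
basic residues" with no upper cap (observed families range roughly five to
eleven, but the rule is a lower bound). Non-standard residues at rule
positions are treated as non-matches and logged. The six categories are
mutually exclusive and exhaustive by construction; aggregate groups (DNA
binders, E-box binders, G-box binders, non-binder group) are sums of
category cells and nest accordingly.

## Intron mapping and the pattern registry

For an intron after `c` spliced-CDS nucleotides, `d = c − domain_cds_start
+ 1` counts the domain-coding nucleotides upstream of it. The intron
belongs to the domain when `1 ≤ d ≤ 3L` (L = domain length in residues);
its codon is `ceil(d/3)` and its phase `d mod 3`, with phase 0 meaning the
intron falls exactly after the named codon. The inclusive right boundary
keeps a phase-0 intron directly after the final domain codon inside the
domain, while a phase-0 intron directly before the first codon (d = 0) is
outside; this makes the planting arithmetic exactly invertible for every
codon 1..L and phase 0..2, which the suite checks exhaustively. Traversal
is in transcription order, so plus- and minus-strand genes yield identical
events.

Signatures are tuples of (position, phase) with positions rescaled to a
60-residue reference so domains of different loop lengths can share a
pattern. Two signatures merge when intron counts match, phases are equal,
and every position pairs within a tolerance (default ±2 residues — the
merging of "highly conserved positions" across genes needs some slack, and
two residues is narrow enough to keep distinct patterns apart at the
registry's scale; it is configurable). Labels are issued in first-encounter
order over lexicographically sorted gene ids, so the assignment is
independent of input order; intronless domains take a reserved label. The
published A–V letter names of any particular study are registry-local and
not recoverable without that study's per-gene data; an alias file can map
registry labels onto published names.

## Conservation

`column_conservation` uses a gap-*inclusive* denominator by default: the
fraction asks "in what share of the domains is this column's modal residue
present", so a mostly-gap column cannot be called conserved in half the
family. This deliberately differs from the scanning consensus (gap-excluded
denominator for *picking* the residue); both variants sit behind a flag and
both choices are documented here because published conserved-position
counts do not state which convention they used.

## Synthetic families

The generator emulates the inputs a genome-scale family study consumes:
protein FASTA with species/chromosome/subgenome metadata, GTF gene models
with exon/CDS rows and frames, spliced CDS FASTA, and a truth table. Study
conditions are encoded in `FamilySpec` defaults: 200 genes; binding-category
mix proportional to the published wheat family table (291/85/84/8/3/100 of
571); loop lengths 5–10 with mode 6 at 64% (domain length mode 60);
intron blueprints covering the common patterns — intronless (20%), a single
phase-0 loop intron (40%), three phase-0 introns at conserved positions
(25%), and a two-intron non-zero-phase pattern (15%); subgenome fractions
0.32/0.35/0.33 with a 3% scaffold rate, mirroring the roughly even
three-way split of a hexaploid genome. Basic-region composition is
rule-forced per category (rule positions set to force the category, free
positions filled to a drawn basic-residue count — 5–11 for binders, below
5 otherwise), so truth categories are consequences of the planted
residues, not labels stored beside them.

Gene models are built by back-translating the protein with a fixed codon
table (first codon per amino acid in lexicographic order) — deterministic
CDS content without a genome — and cutting introns at the blueprint
offsets; intron lengths are uniform 60–300 nt (published lengths vary
widely even at one position, and lengths do not affect patterns); strands
are drawn 50/50 and minus-strand models are coordinate-mirrored; the stop
codon is excluded from the CDS. Exons equal CDS intervals (no UTRs), which
is the only gene-model feature downstream stages consume.

Per-gene random streams are keyed by (seed, gene index). Substitution noise
applies per position outside the four rule positions; the decision draw is
consumed whether or not it fires, so the corrupted position sets at a lower
rate nest inside those at a higher rate and recovery degrades monotonically
in the rate on a fixed seed.

Expression values are log-normal around class means (tissue-specific genes
clear 10 units only in their own tissue, broad genes everywhere, silent
genes capped below 5), and the differential-expression table is *generated*
— planted log2 fold change plus gaussian noise of scale `dispersion`
(default 0.25), adjusted-p placeholders drawn well below 0.05 for regulated
genes and well above for null genes. Count-model fitting is out of scope;
the downstream filters consume only thresholds, so a threshold-faithful
table is sufficient. Consequently, passing tests demonstrate correctness of
the coordinate arithmetic, rules and filters on data with the declared
structure; they do not exercise alignment-noise artifacts, fragmented gene
models, UTR-containing exons, or count-level statistical behavior of real
RNA-seq.

## Numerical and formatting choices

All printed percentages are rounded half-up to two decimals. Thresholds
keep their documented strict/inclusive semantics: expression inclusion is
strictly > 10 for TPM and ≥ 5 for FPKM/RPKM (the mixed semantics follows
the conventions of the data sets these thresholds come from and is
deliberately preserved); DEG selection is |log2FC| ≥ 1 and adjusted
p ≤ 0.05, both inclusive. Representative-transcript selection minimizes
mismatches, then maximizes protein length, then takes the lexicographically
smallest transcript id. Report assembly writes no timestamps, so identical
inputs and configuration produce byte-identical bundles.

## Problem sizes

The suite and the acceptance script run at desk scale by design: families
of 50–200 genes, 100 replicate expression draws for effect-recovery
checks, exhaustive intron planting over 60 codons × 3 phases, and
brute-force placement verification on 50 proteins. These sizes make every
check exact or tightly bounded while completing in seconds.

## Known limitations

* The scanner does not model insertions/deletions inside the domain beyond
  the elastic loop; a gapped candidate would need alignment-based scoring.
* The pattern registry reproduces the taxonomy *mechanism*; label letters
  are not comparable across registries without an alias map.
* Conservation statistics summarize single columns; covarying positions
  and evolutionary rates are out of scope.
* The binding categories are sequence-rule predictions, not biochemistry;
  genuinely divergent binders will be misclassified by any residue rule.
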