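# Methods

## Design model

The designer treats a library as a set of independently cloned fragments.
The target is an in-frame CDS embedded in a linear construct
`upstream context + CDS + downstream context` (user-supplied backbone
sequence, or an 80-nt deterministic site-free context generated from a
fixed internal seed). Coordinates are 1-based codon indices; nucleotide
offsets are 1-based inclusive.

**Domestication.** Internal BsaI (GGTCTC) and BsmBI (CGTCTC) sites on
either strand are removed before design. Sites are processed 5'→3';
overlapping codons are tried left to right and synonymous replacements in
descending codon-usage order; the first swap that strictly reduces the
total site count is kept. The tie-break (left-to-right, usage-ranked) is a
design choice of this package; domestication is idempotent and never
changes the protein. The bundled usage table is a human high-frequency
table (normalized per amino acid on load); any two-column TSV can replace
it.

**Geometry.** Default synthesis profile: 230-nt oligos, 18-nt subpool
primers, 6+1-nt recognition+spacer per cassette, 4-nt overhangs, 4
wild-type flank codons per side, and platform indel caps of 120 nt
(insertion) / 27 nt (deletion), enforced as profile constants. The
largest mutable window is

    L_max = floor((230 − 2·25 − 24 − max_ins) / 3)

where `max_ins` is the longest configured insertion payload (9 nt at the
defaults), giving 49 codons. The overhangs are wild-type gene sequence and
therefore counted inside the fragment, not the cassette; this accounting
guarantees that the longest (insertion) variant of a maximal window is
exactly 230 nt. A 436-residue ORF thus partitions into 9 near-equal
sublibraries (windows differ by ≤1 codon).

**Variant set.** Per residue of the window: 19 missense substitutions;
one synonymous swap when the wild-type amino acid has ≥2 codons; an
optional stop (off by default — the 26-variants-per-residue arithmetic
excludes it); one insertion per configured payload placed immediately 3'
of the residue (defaults encode G, GS, GSG with top-ranked human codons);
and one deletion per configured length (1–3 codons) starting at the
residue. Deletion starts exclude codon 1 and run only to `L − max_del`,
one shared range for all lengths, so deletions stop short of the C
terminus. Names are HGVS-protein-like (`p.L28A`, `p.A12=`, `p.K7_insGS`,
`p.A12_G14del`) and unique per design.

**Codon choice and site rescue.** Missense/stop/synonymous codons are the
highest-usage codon that does not complete a recognition site in context.
When every codon completes a site, the fewest-site codon is used and the
site is then *rescued*: a codon overlapping the new site is synonymously
recoded (usage-ranked, never reverting a synonymous variant to wild type).
Deletion junctions can likewise fuse sequence into a new site and are
rescued the same way. Rescue prefers codons inside the mutable window; as
a last resort a flank codon may be recoded provided it does not overlap a
junction overhang — the assembled protein is unaffected in every case, and
all extra synonymous edits are recorded in the variant's nucleotide
signature. Insertion payload codons may also be recoded (the inserted
amino acids are preserved).

**Overhang selection.** Each junction overhang is the wild-type 4-mer at
the fragment boundary. A depth-first search over per-junction slides
(1-nt steps; up to 8 nt inward on the 5' side, up to 2 nt inward on
internal 3' junctions — capped so a terminal-window deletion can never
reach the overhang — and up to 12 nt outward when the sublibrary has
synthesis-length slack) finds an assignment in which all overhangs are
pairwise distinct, non-palindromic, and not reverse complements. The
search is deterministic; an exhausted search raises `NoValidOverhangs`.

**Oligo layout and buffering.** Each oligo is
`fwd_primer | buffer5 | cassette5 | fragment | cassette3 | buffer3 |
rev_primer`. All oligos of a sublibrary share one synthesis length — that
of the longest-insertion variant — with filler split evenly 5'/3' (odd
remainder 3'). Filler comes from a deterministic pseudorandom pool
(40–60% GC, screened against both enzymes); a finished oligo must contain
the recognition sequence exactly twice (its two cassettes) and no 12-mer
shared with any primer, retrying filler offsets otherwise.

**Primers.** Subpool barcodes are drawn from a deterministically generated
orthogonal set (18-mers, 40–60% GC, no enzyme sites, pairwise 3'-end
identity ≤8 nt, nearest-neighbor Tm ≥ threshold). Backbone inverse-PCR
primers anneal immediately outside the fragment with 5' cassette tails
whose digestion exposes the complementary junction overhangs; annealing
regions extend up to 40 nt until Tm ≥ 58 °C. Tm is SantaLucia
nearest-neighbor at 50 mM monovalent salt and 250 nM primer
(Biopython `Tm_NN`).

## Assembly simulation

Digestion requires exactly one recognition site per strand in convergent
orientation; the insert retains the two single-stranded 4-mers located one
spacer beyond each recognition sequence. The backbone amplicon is modeled
as two linear arms around the excised fragment (sufficient for intent
verification; no circular plasmid graph). Ligation is exact-complement
only — no mismatch model, matching the fidelity assumption of Type IIS
assembly. The audit reconstructs the full CDS of every variant, translates
it, and compares against the wild-type protein with exactly the intended
edit applied; `verify_design` reports designed/assembled counts, in-frame
and intent-match fractions, residual enzyme-site counts, and per-sublibrary
breakdowns, counting failures rather than raising.

## QC statistics

Counts come in as `(genotype, count)` rows with nucleotide-level genotype
strings (`84_85insGGC`, `82G>C;84T>G`, …). Designed variants are matched
by exact canonical signature (including rescue edits); everything else is
binned: deletions and insertions into nt-length classes {1, 2–3, 4–30,
>30} (configurable — the class boundaries are this package's
interpretation), single point changes into synonymous vs missense
(stop-gain counts as missense), and multi-op reads into `multiple`.
Malformed strings are reported, never fatal.

Coverage balance uses per-position totals and per-sublibrary medians; the
fold-range is max/min of the medians (infinite with a warning when a
median is zero). The Gini coefficient is `1 − 2·AUC` of the
ascending-sorted Lorenz curve (trapezoidal), identical to the pairwise
mean-absolute-difference form and scale-invariant. Between-kind bias is
tested with two-sided Welch t-tests on per-position mean read frequencies,
adjusted by Benjamini–Hochberg (the adjustment method is configurable to
Bonferroni; the choice of BH is ours), with significance stars at
0.05/0.01/0.001.

## Score analyses

Score tables are Enrich2-style (HGVS-like identifier, score, SE, optional
`score_rep*` columns); rows scored in fewer than all replicates can be
filtered with `complete_replicates()`, and the Gly-correlation can be run
on either the filtered or unfiltered table. The insertion-vs-substitution
comparison pairs positions having both a 1-residue Gly insertion and an
X→Gly missense score and reports Pearson r. Structure comparisons use the
two-sided Wilcoxon rank-sum test: exact null distribution when both
samples are ≤50 with no ties, tie-corrected normal approximation
otherwise; fully tied data returns p = 1.

Evolutionary indel conservation reads HMMER3 profiles with pyhmmer; the
per-match-state m→i and m→d transition probabilities are decoded from the
file's negative-log text fields in double precision (the profile object
stores float32). Match states map onto the target by local BLOSUM62
alignment (gap open −11, extend −1) of the profile consensus; <50% mapped
coverage warns, and overlapping profiles never overwrite earlier
positions. Probabilities are binarized at 0.1 (exposed; the cutoff is
pseudo-binary by nature and our choice) and cross-tabulated against the
sign of the per-position mean indel score; association is tested with
two-sided Fisher's exact (minimum-likelihood rule). Degenerate tables
give p = 1 with a warning.

## Synthetic data

`random_gene` draws a uniform random protein (Met start) and steers codon
choice toward a GC target, swapping random internal residues toward
GC-compatible amino acids when the target is extreme; realized GC must be
within ±3% or the call errors. `simulate_counts` distributes multinomial
reads over designed variants with per-sublibrary log-normal mixing factors
`exp(σ·z_s)` (z drawn once per seed, so bias is monotone in σ) and injects
off-target genotypes at a configured fraction (default 20%, echoing what
oligo-pool synthesis errors leave in real libraries) with a
deletion-dominated class mix. `simulate_scores` draws
`kind mean + shared position effect + noise`, defaults ordering deletions
< insertions < missense < synonymous with the synonymous mean at 0.
Everything is reproducible from a single seed.

What the generators do **not** emulate: sequencing error at the read
level, position-dependent synthesis error rates along the oligo,
replicate-specific selection bottlenecks, or any real biology linking
scores to structure. Passing tests therefore demonstrate the
correctness of the design/assembly/statistics machinery, not biological
validity on real screens.

## Problem sizes and numerical choices

The test suite exercises designs up to 600 codons and verifies full
round-trip completeness (intent-match 1.0, zero residual sites) on 20
random genes of 30–500 codons and 35–65% GC; the calibration script uses
a single 436-residue ORF. Statistical kernels are validated against
brute-force oracles (pairwise-difference Gini at 1e-12; exhaustive
rank-permutation Wilcoxon at n≤8; hypergeometric-enumeration Fisher for
margins ≤20). Floating-point tolerances elsewhere are stated per test.

## Known limitations

* The backbone is linear; circular-plasmid effects (e.g. re-ligation
  kinetics) are out of scope.
* Ligation fidelity is all-or-nothing; near-cognate overhang mismatches
  are not modeled.
* One gene per design; multi-gene pooled synthesis on a shared chip is
  not optimized.
* Secondary-structure annotations are inputs (TSV); nothing is derived
  from 3-D structures.
* Enrich2 scoring itself is not reimplemented — only its outputs are
  consumed.
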