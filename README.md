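# indelkit

Deep mutational scanning (DMS) has mostly been a missense-only technology,
even though insertions and deletions make up a large share of naturally
occurring and disease-causing protein variation. The practical obstacle is
library construction: inverse-PCR mutagenesis cannot program indels without
per-variant primers, and transposon approaches are biased and incomplete.
`indelkit` is a design and in-silico verification toolkit for the
microarray-oligo route around this problem: every variant — each of the 19
missense substitutions per residue, a synonymous codon swap where the amino
acid allows one, an optional stop, 1–3-codon deletions, and programmed
insertions (Gly, Gly-Ser, Gly-Ser-Gly by default) — is individually
synthesized in a ≤230-nt oligo pool and cloned into the target by Type IIS
(Golden Gate) assembly. It is written for groups building indel-containing
DMS libraries and analyzing the screens they produce.

## What the package does

**Design** (`sequence_model`, `design_core`): load an in-frame ORF
(FASTA/GenBank), *domesticate* it (remove internal BsaI/BsmBI recognition
sites by synonymous, codon-usage-ranked substitutions), partition the
mutagenesis window of $L$ codons into
$N = \lceil L / L_\text{max} \rceil$ sublibrary fragments, where

$$L_\text{max} = \left\lfloor \frac{L_\text{oligo} - 2(\ell_\text{primer} + \ell_\text{rec+spacer}) - 6\,\ell_\text{flank} - \max_v |\text{ins}_v|}{3} \right\rfloor$$

($L_\text{oligo}=230$, 18-nt subpool primers, 7-nt recognition+spacer per
cassette, 4 non-mutated wild-type codons flanking each cut site, 9-nt
longest default insertion, giving $L_\text{max}=49$). Each fragment
junction gets a wild-type 4-nt overhang; cut sites slide a few nucleotides
so that all overhangs in a design are unique, non-palindromic, and not
reverse complements of each other. Every variant becomes one oligo —
`primer | buffer | cassette | flank | payload | flank | cassette | buffer |
primer` — with buffers equalizing all oligos of a sublibrary to one
synthesis length so short deletion species are not favoured during PCR.
Orthogonal barcode primer pairs amplify each sublibrary from the pool, and
inverse-PCR backbone pairs (nearest-neighbor $T_m \ge 58\,^\circ$C) add the
complementary cut sites to the vector.

**Verify** (`assembly_sim`): every oligo is digested and ligated in silico
(exact-complement overhangs only) and the reconstructed CDS is translated
and compared to the wild-type protein carrying exactly the intended edit.
A correct design reports an intent-match fraction of 1.0 and zero residual
enzyme sites.

**QC** (`library_qc`): from a variant-caller count table, per-position
coverage and per-sublibrary median fold-range, Lorenz curves and the Gini
coefficient $G = \sum_{i,j}|x_i-x_j| \,/\, (2n^2\bar x)$ (0 = perfectly
even library), Welch t-tests between variant kinds with Benjamini–Hochberg
adjustment, and classification of non-designed reads into error classes
(deletions/insertions by length bin, synonymous/missense point errors,
multi-error reads).

**Analyze** (`scores_analysis`): Enrich2-style fitness tables parsed by
HGVS-like name; per-kind score distributions; Pearson correlation of
Gly-insertion vs X→Gly-substitution scores at the same position; Wilcoxon
rank-sum comparisons across secondary-structure strata; and Fisher's exact
association between experimentally tolerated indel positions and
evolutionary indel positions read from a profile HMM's match→insert and
match→delete transition probabilities.

**Simulate** (`fixtures`): seeded generators for GC-controlled random ORFs,
count tables with configurable off-target fraction and per-sublibrary
log-normal mixing bias, score tables with a per-kind effect hierarchy, and
small synthetic HMMER3 profiles — every stage is testable offline.

## Worked example

```bash
indelkit fixtures --seed 1 --n-codons 60 --out demo      # synthetic inputs
indelkit verify --gene demo/gene.fasta
indelkit qc --gene demo/gene.fasta --counts demo/counts.csv --out demo/qc.json
```

prints

```
designed=1539 assembled=1539 in_frame=1.0000 intent_match=1.0000 residual_sites=0
designed_fraction=0.8007 gini=0.0488 fold_range=1.155
```

The 60-codon gene yields 1539 variants across 2 sublibraries (each
interior residue contributes 26: 19 missense + 1 synonymous + 3 insertions
+ 3 deletions). All 1539 assemble in frame to exactly the intended
protein with no stray enzyme sites. The simulated sequencing run was
configured with 20% off-target reads, and QC recovers a designed-read
fraction of 0.80; a Gini of 0.049 and a sublibrary median fold-range of
1.16 describe a well-balanced library (< 2-fold is the usual bar).

The same pipeline is available as a library:

```python
from indelkit import design_library, verify_design, random_gene

design = design_library(random_gene(436, 0.50, seed=1))
print(len(design.sublibraries))          # 9
print(verify_design(design).intent_match_fraction)  # 1.0
```

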