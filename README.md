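# hopperpath

Pathway-level contrast analysis of rice transcriptional responses to
small brown planthopper (SBPH, *Laodelphax striatellus*) infestation.

## The problem

When a phloem-feeding insect attacks a plant, which individual metabolic
pathways respond — and which of those responses distinguish a resistant
genotype from a susceptible one?  A common design compares a resistant
line (R) and a susceptible line (S) before (0 h) and after (6 h)
infestation, yielding four pairwise expression contrasts:

| label   | comparison                         | kind     |
|---------|------------------------------------|----------|
| `R6_R0` | 6 h vs 0 h in the resistant line   | temporal |
| `S6_S0` | 6 h vs 0 h in the susceptible line | temporal |
| `R0_S0` | R vs S before attack               | genotype |
| `R6_S6` | R vs S after attack                | genotype |

`hopperpath` takes per-contrast tables of differentially expressed (DE)
genes (fold change + q-value), a BioCyc-style pathway–gene association
table and a probe→locus map, and turns them into pathway-level
biology:

1. **Filter** — a gene is DE when its expression ratio is ≥ 2 (or ≤ 1/2)
   with q < 0.05.
2. **Call** — a pathway is *differentially regulated* in a contrast when
   ≥ 1 DE gene maps to it; its direction is **up** if every DE member
   gene is up, **down** if every one is down, **up/down (mixed)**
   otherwise.  Genotype contrasts render as higher/lower (R over S).
3. **Partition** — called pathways are placed in the 15 cells of the
   four-contrast Venn diagram.
4. **Classify** — rule-based classes nominate candidate pathways:

   * *Class I*: regulated in `R6_R0` but not `S6_S0`; genotypes differ
     after attack (`R6_S6`) but not before (`R0_S0`).
   * *Class II*: as Class I, but the genotypes also differ before attack.
   * *Class III*: regulated in both genotypes with strictly opposing pure
     directions, and a genotype difference after attack.

   Susceptibility classes swap the roles of `R6_R0` and `S6_S0`;
   Class III is shared between the two axes.

A companion module recomputes free-amino-acid percent changes
(`100 × (after − before) / before`, one decimal, half away from zero)
from the packaged concentration table, and a simulator generates fully
synthetic input bundles with planted, recoverable regulation patterns —
the original microarrays are not publicly deposited, so the simulator is
how the pipeline is exercised end to end.

## Worked example

Classify the packaged direction grid of the 25 pathways curated from the
R (introgression line Pf9279-4) vs S (cv. 02428) infestation study:

```sh
$ hopperpath classify -o classes.tsv
resistance classes — I: 8, II: 11, III: 2, any: 21
susceptibility classes — I: 0, II: 4, III: 2, any: 6
```

21 pathways are resistance-associated (8 induced only in R with no
constitutive genotype difference, 11 with one, 2 opposing between
genotypes) and 6 susceptibility-associated; the two Class III pathways
(ureide biosynthesis, phenylalanine degradation III) appear on both
axes.  `classes.tsv` lists each pathway with its classes and its four
rendered direction calls.

Amino-acid percent changes from the packaged concentration table:

```sh
$ hopperpath aa-changes -o aa_changes.tsv
total change: S6_S0 -47.0%, R6_R0 1.3%
largest resistant increases: γ-Amino-n-butyric Acid, Tyrosine
discrepant rows: Aspartic acid, Cystathionine, Cystine, Methionine, Serine
```

Total free amino acids drop 47% in the susceptible line but barely move
in the resistant one; GABA (+895.7%) and tyrosine (+297.3%) rise most in
the resistant line.  The "discrepant" analytes are rows whose published
change columns cannot be reproduced from their published concentrations;
they are flagged in `aa_changes.tsv`, not silently corrected.

Simulate a bundle with planted patterns and run the full pipeline:

```sh
$ hopperpath simulate -c sim.yaml -o bundle/
wrote bundle to bundle/: 30 pathways, 3 planted patterns
$ hopperpath run --bundle bundle/ -o results/
called 3 pathways; resistance classes {'I': 1, 'II': 0, 'III': 1, 'any': 2}; susceptibility classes {'I': 0, 'II': 1, 'III': 1, 'any': 2}
```

`results/` then holds `pathway_calls.tsv`, `patterns.tsv`, `venn.tsv`,
`classes.tsv`, `category_counts.tsv`, `network.tsv` and a
`manifest.json` with input hashes and thresholds.  With zero background
noise the recovered classes equal the `truth.tsv` the simulator wrote.

The same operations are available as a library
(`hopperpath.filter_significant`, `call_pathways`, `build_patterns`,
`venn_partition`, `classify_resistance`, …); see the module docstrings
and `docs/methods.md`.

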