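# cneduo

Analysis toolkit for a duplicated pair of conserved noncoding elements
(CNEs) in paralogous Hox-like gene clusters — the situation exemplified by
the 32-nt element inside the *HOTAIR* locus (HoxC cluster) whose paralog
sits in the promoter of a noncoding *HOXD11* transcript (HoxD cluster),
the two copies descending from one ancestral element through the second
round of whole-genome duplication.

The package is written for computational biologists who want to test, on
their own loci or on fully controlled synthetic data, the chain of
inference such a dual *cis*/*trans* regulatory story rests on:

1. **Discovery** (`cneduo.discovery`) — seed-and-extend ungapped homology
   scan of a query element against per-species genomes on both strands,
   synteny assignment (a hit belongs to cluster C or D when it lies
   strictly between that cluster's gene11 and gene12), and a cross-species
   presence/absence matrix.
2. **Complementarity & compensatory substitutions**
   (`cneduo.complementarity`) — the two copies are written 5′→3′ in
   host-transcript orientation; column *i* of the C copy is complementary
   when it Watson–Crick pairs with column *L*−1−*i* of the D copy
   (antiparallel hybridization), so the score is
   *matches*(seq_C, revcomp(seq_D))/*L*. Ancestral states for every
   column of both copies are reconstructed by Fitch parsimony on a
   species tree; a branch carrying substitutions on **both** copies at a
   paired column is a compensatory call, classed as *gain*, *retention*
   or *loss* of complementarity.
3. **Intron retention** (`cneduo.retention`) — spliced reads are
   classified against one transcript model as exon / intron / junction /
   unassigned; retention is (intron+junction)/(exon+intron+junction) and
   nuclear enrichment is log₂(nuclear/cytosolic) of those fractions.
4. **Enhancer state** (`cneduo.regulatory_state`) — CAGE transcription
   start sites are clustered per strand, divergent (−,+) cluster pairs
   around the element are tested for nucleosome-scale spacing, and a
   deterministic ladder over DNase openness, H3K4me1 bimodality, H3K27ac,
   H3K27me3 and eRNA evidence calls *closed*, *poised_enhancer*,
   *active_enhancer*, or *promoter_ambiguous* (an element inside an
   annotated promoter is never called from signals alone).
5. **Co-expression** (`cneduo.coexpression`) — element-vs-gene
   correlations (Pearson on log₂(TPM+1), or Spearman) on the subset of
   samples where both features are expressed, with Benjamini–Hochberg
   q-values; plus noncoding/coding promoter usage ratios with a sign
   test.
6. **Synthetic data** (`cneduo.synthetic`) — a fully seeded generator
   that plants every quantity above (element copies, compensatory events,
   retention fraction, divergent TSS spacing, chromatin states, expression
   couplings) and records the truth in a ledger, so each stage can be
   scored against known ground truth.

## Worked example

Run the shipped demo: it simulates a four-species clade with two planted
compensatory events, 40 % intron retention, three chromatin states, and
planted expression couplings (+0.9, +0.5, −0.3, −0.9), then runs every
analysis stage and scores it against the truth ledger:

```bash
cneduo run --config configs/demo.yaml --out demo_run
```

```
report: demo_run/report.json
  compensatory_precision: 1.0000
  compensatory_recall: 1.0000
  correlation_sign_recovery: 1.0000
  discovery_recovery: 1.0000
  orientation_accuracy: 1.0000
  promoter_ratio_abs_error: 0.0601
  retention_abs_error: 0.0050
  spacing_abs_error_bp: 0.0000
  state_accuracy: 1.0000
```

Every score compares a pipeline result with the planted truth: all eight
element copies were rediscovered with the correct cluster label
(`discovery_recovery`), both planted compensatory events were called on
the right branch, columns and class (precision/recall), the estimated
whole-cell retention fraction missed the planted 0.4 by 0.005, the three
planted chromatin states were all called correctly and the planted
180-bp divergent spacing was measured exactly, and every planted
coupling sign was recovered. `demo_run/correlations.tsv` holds the
correlation table:

```
element  gene    n    r        p          q          subset_rule
CNE      HOXC11  103   0.898   1.1e-37    4.3e-37    co-expressed
CNE      HOXC12  102   0.489   1.9e-07    2.5e-07    co-expressed
CNE      HOXD11  100  -0.204   4.1e-02    4.1e-02    co-expressed
CNE      HOXD12  102  -0.884   1.0e-34    2.1e-34    co-expressed
```

— the positive-*cis* / negative-*trans* contrast, estimated only on
samples where both features exceed 1 TPM. The same directory contains
the presence/absence matrix, per-state enhancer calls
(`closed / poised_enhancer / active_enhancer`), retention fractions per
compartment (whole-cell 0.395, nuclear 0.398, cytosolic 0.038,
log₂ nuclear/cytosolic ≈ 3.4), and the truth ledger.

Each stage is also a standalone subcommand (`cneduo simulate`,
`discover`, `compensate`, `retention`, `state`, `correlate`); see
`cneduo <cmd> --help`.

## Documentation

`docs/methods.md` describes the models and procedures, the generator's
assumptions and what it deliberately does not emulate, all tunable
parameters with their defaults, and known limitations.
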