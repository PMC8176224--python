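# cernapipe

Cross-species co-differential expression and competing-endogenous-RNA
(ceRNA) network inference, with a synthetic ground-truth simulator for
end-to-end validation.

## The problem

Comparative transcriptome studies of high-altitude adaptation contrast a
low-altitude cattle population (LAC) with a high-altitude cattle
population (HAC) and with yak (LWQY), three biological replicates each,
across four RNA classes (mRNA, lncRNA, miRNA, circRNA). The analytical
core downstream of quantification is:

1. **Class-specific differential expression** — mRNA and lncRNA are
   called at BH-adjusted FDR < 0.05 with |log2FC| ≥ 1; miRNA and circRNA
   at raw *P* < 0.05 with the same fold-change gate.
2. **Ortholog-mapped co-differential intersection** — yak results are
   projected onto cattle gene ids through a one-to-many ortholog map
   (one cattle id ↔ one or more yak ids) and intersected across the
   LAC-vs-HAC and LAC-vs-LWQY comparisons, with direction agreement and
   Venn summaries.
3. **lncRNA association rules** — candidates (> 200 nt, > 2 exons) are
   related to genes as *antisense* (opposite-strand overlap), *cis*
   (within 10 kb up/downstream), or *trans* (co-expression, Pearson
   r > 0.9).
4. **ceRNA inference** — a pair (A, B) is a ceRNA pair iff both are
   co-DE, both are anticorrelated targets (Spearman ρ < −0.7) of at
   least one common miRNA, their mutual Pearson r > 0.9, and the
   **hypergeometric sponge test** on their shared regulator miRNAs is
   significant at *p* < 0.05:

   p = P(X ≥ x) = Σ_{k=x}^{min(M,N)} C(M,k)·C(U−M,N−k) / C(U,N)

   where *x* is the number of miRNAs regulating both A and B, *M* and
   *N* are the sizes of A's and B's full regulator sets, and *U* is the
   total number of miRNAs identified.
5. **Enrichment and reporting** — one-sided Fisher exact
   over-representation against GMT term maps (the same hypergeometric
   kernel), plus the study-style summary arithmetic (detection
   percentages of a reference catalogue, novel/known expression ratios,
   up/down tallies).

Because the real inputs require a sequencing experiment and external
target predictors, the package ships a first-class **simulator** that
plants known fold-changes, miRNA-mediated repression, and ceRNA
triplets, and emits the ground truth needed to score every stage.

## Worked example

```python
import cernapipe as cp

result = cp.run_all(cp.SimulationConfig(seed=7))
print(result.report)
print(result.scores["triplets"])
```

prints (abridged):

```
## co-differential expression
circRNA  venn=(3,3,14)   up=9   down=5   total=14  conflicts=0
lncRNA   venn=(6,1,13)   up=6   down=7   total=13  conflicts=0
mRNA     venn=(17,17,34) up=20  down=14  total=34  conflicts=0
miRNA    venn=(1,0,29)   up=11  down=18  total=29  conflicts=0

## ceRNA network
nodes=31  circRNA=4  lncRNA=3  mRNA=7  miRNA=17
edges=37  cerna_pair=7  mirna_target=30

{'precision': 1.0, 'recall': 0.875, 'n_predicted': 7, 'n_planted': 8}
```

Reading this: per class, `venn=(a,b,shared)` counts transcripts
significant only in LAC-vs-HAC, only in LAC-vs-LWQY, and in both; the
network contains 7 ceRNA pairs, each backed by a significant sponge
test, e.g.

```
      gene_a       gene_b  x  M  N   U        p      pcc
BT_CIRC_0060 BT_MRNA_0126  3  4  3 120 0.000014 0.998709
```

— this circRNA and mRNA share x = 3 regulator miRNAs out of regulator
sets of 4 and 3 in a universe of U = 120, which under the hypergeometric
null has p ≈ 1.4e-5; their expression correlates at r ≈ 0.999. Of the 8
planted triplets, 7 were recovered and nothing spurious was reported
(precision 1.0, recall 0.875 for this seed).

The same pipeline is available from the shell:

```sh
cernapipe run-all --seed 7 --outdir out/
cernapipe simulate --seed 7 --outdir fix/
cernapipe de --fixture fix/ --outdir out/de/
cernapipe codiff --fixture fix/ --de-dir out/de/ --outdir out/co/
```

All thresholds live in a YAML config (`--config`); the effective
configuration is echoed into the output directory.

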