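# Methods

## Study design being modelled

Three groups — low-altitude cattle (LAC, the reference), high-altitude
cattle (HAC), and yak (LWQY) — with three replicates each, quantified as
TPM-like abundances for four RNA classes. Two comparisons are made, LAC
vs HAC (within cattle ids) and LAC vs LWQY (on yak ids, then projected
to cattle ids through a one-to-many ortholog map), and downstream
analysis is keyed on cattle ids. The third possible comparison (HAC vs
LWQY) is deliberately absent from the design.

## Generative model

All structure lives on the log2 scale. For transcript *t* and sample
*s*:

    x_ts = b_t + delta_t·1[s ∈ {HAC, LWQY}] + e_ts

with baseline b_t ~ N(mu_base, sigma_base) = N(5, 1.5), residual
e_ts ~ N(0, noise_sd) with noise_sd = 0.25, and delta_t = ±de_log2fc
(2.0) for the planted-DE fraction (frac_de = 0.25 per class), zero
otherwise. A configurable fraction of planted effects
(frac_shared_de = 0.6) applies to both high-altitude groups (making the
transcript co-DE); the remainder applies to HAC only or LWQY only,
populating the exclusive regions of the Venn diagrams.

Each planted ceRNA triplet consists of one mRNA partner, one lncRNA or
circRNA partner (alternating), and min_shared_mirnas = 3 shared miRNAs
planted DE in one common direction. Repression is multiplicative on the
linear scale — additive in log2:

    x_ps = b_p − repression_beta · Σ_{m ∈ S} (x_ms − b_m) + e_ps

with repression_beta = 1.5. Because the miRNA *deviation* (group shift
plus its own noise) propagates into both partners with a negative sign,
partners co-vary positively with each other and negatively with their
miRNAs — the two correlation signatures the inference stage gates on.
Partners receive no direct DE effect; their differential expression is
entirely repression-induced, with direction opposite to their miRNAs.

Yak abundances are ortholog copies: each cattle id maps to 1..2 yak ids
(ortholog_multiplicity_max = 2), each copy being the cattle log2 value
plus N(0, divergence_sd = 0.1). The yak matrices carry LAC and LWQY
columns so that the LAC-vs-LWQY comparison is computed on yak ids first
and then projected — mirroring a workflow in which yak samples are
quantified against the yak annotation.

Abundances are exported as 2^x on a TPM-like scale. They are **not**
renormalised to 10^6 per sample: renormalisation would couple all
transcripts through the library-size denominator and contaminate the
planted correlation structure. This is a documented deviation from
strict TPM.

The target map contains the planted triplet edges, 0–2 private (non-DE)
regulators per partner (so M and N exceed x), and 3 random decoy targets
per miRNA. The ortholog map, annotation coordinates, and GMT terms
(carved from the planted truth plus random null terms) complete the
bundle. A single integer seed fully determines every output.

### Simulator defaults and why

| parameter | default | rationale |
|---|---|---|
| replicates_per_group | 3 | the modelled study design (n = 3 healthy individuals per group) |
| n_mrna / n_lncrna / n_mirna / n_circrna | 300 / 80 / 120 / 80 | small enough for fast tests, large enough for meaningful BH adjustment; the miRNA count accommodates 8 triplets × 3 shared miRNAs within the DE fraction |
| frac_de | 0.25 | realistic DE fraction for a strong between-population contrast |
| de_log2fc | 2.0 | comfortably above the |log2FC| ≥ 1 gate, as published effects are |
| repression_beta | 1.5 | strong repression; generates both required correlation signs |
| noise_sd | 0.25 | makes |SCC| > 0.7 attainable but non-trivial at n = 9 |
| divergence_sd | 0.1 | small enough to preserve co-DE direction agreement across species |
| n_triplets | 8 | bounded by the planted-DE miRNA budget (frac_de·n_mirna ≥ 24) |
| min_shared_mirnas | 3 | with U = 120 and regulator sets of ~4–7, x = 3 gives sponge p ≪ 0.05; x = 2 would sit near the 0.05 boundary and make recovery fragile |

### What the simulator does and does not emulate

It emulates the *statistical* structure the pipeline consumes: group
design, fold-changes, class membership, ortholog multiplicity,
miRNA-mediated anticorrelation, partner co-expression, positional
lncRNA classes (cis within 10 kb, antisense overlap, distal), and a
target map with decoys. It does **not** emulate read-level sequencing,
sequence content, isoform structure beyond exon counts, library-size
normalisation artefacts, overdispersed count noise (values are
log-normal, not negative binomial), or miRNA seed-match realism.
Passing tests therefore demonstrate that the pipeline's logic recovers
planted structure under Gaussian log-scale noise — not that it is robust
to the full error structure of real RNA-seq.

## Differential expression

Fold change is log2((mean_B + 1)/(mean_A + 1)) on TPM means
(pseudocount 1 TPM; none is standard, one is conventional).
Significance comes from a two-sided Welch unequal-variance t-test on
log2(TPM + 1), with per-group variances floored at 1e-8 so that
zero-variance groups remain testable rather than special-cased. The DE
engine of the original workflow is an external count-model package and
is out of scope here; the Welch stand-in is isolated behind `de_test`
so it can be swapped. The |log2FC| ≥ 1 boundary is inclusive, as
written. BH adjustment is computed per comparison per RNA class.

At n = 3 per group the Welch test is slightly conservative (empirical
type-I ≈ 0.03–0.04 at nominal 0.05), and its Satterthwaite degrees of
freedom collapse toward 2 when repression drives one group near zero
TPM (the log2(TPM+1) values saturate near 0 with tiny variance). This
is why a planted partner occasionally lands just above the FDR cut in
one comparison — the dominant source of imperfect triplet recall.

## Ortholog projection and intersection

A cattle id is significant iff **any** mapped yak transcript is
significant (the most inclusive aggregation; "all" is available). The
many-to-one collapse implies some rule and none is canonical; "any" is
the documented default. Direction is the unanimous direction of the
significant mapped copies; disagreement flags the id as conflicting.
Jointly significant ids with opposite directions between the two
comparisons are excluded from the co-DE set but preserved and reported.
Orientation is fixed as (LAC reference vs high-altitude), so "up" means
higher at altitude in both comparisons.

## lncRNA association

Candidates: length > 200 nt and > 2 exons, both strict as specified —
note this is stricter than the common ≥ 2-exon convention; both knobs
are configurable. Coordinates are 1-based inclusive (GTF convention).
The gap between disjoint intervals is the count of bases strictly
between them; "within 10 kb" is inclusive at exactly 10,000. Antisense
requires ≥ 1 bp opposite-strand overlap; sense-strand overlaps are
reported separately. Trans is Pearson r > 0.9 on log2(TPM+1) (the
threshold reuses the ceRNA co-expression value; no trans-specific value
is canonical). Relation precedence is antisense > cis > trans so no
pair carries two relations. Hybridisation-energy prediction is out of
scope; the positional and correlation rules are its stand-ins.

## ceRNA inference

Spearman correlations are computed on TPM directly (rank-based, hence
invariant to monotone transforms); Pearson correlations on log2(TPM+1),
where linearity is more plausible. Both gates are strict inequalities
(ρ < −0.7, r > 0.9), as specified. Correlations use all nine samples
after ortholog merging (LAC + HAC from cattle, LWQY as the mean over
mapped yak copies); the sample universe for correlation is not
canonical, and nine points make the thresholds attainable but
non-trivial — a six-sample (single-comparison) universe is available
via `correlation_groups`.

The sponge test reads "1 − F(x/U, M, N)" as the upper tail
P(X ≥ x) = 1 − CDF(x − 1): using CDF(x) would assign p < 1 to pairs
sharing zero miRNAs, contradicting the test's purpose; the alternative
reading is available via `tail="above"`. The tail sum is evaluated in
exact integer arithmetic (Python `math.comb`), so it agrees rationally
with draw enumeration. x, M, N are taken from the full predicted target
map restricted to the miRNA universe; U defaults to the number of
miRNAs in the expression universe and is overridable. Selection is at
raw p < 0.05 (no multiple-testing correction, matching the published
procedure); a BH option exists and is off by default. Partner classes
default to lncRNA–mRNA and circRNA–mRNA pairs; mRNA–mRNA competition is
possible in principle but disabled by default. Candidate partners must
be co-DE by default (`require_co_de`); passing a wider DE set supports
the looser "DE in either comparison" reading.

Subnetwork extraction takes an induced subgraph within a breadth-first
radius (default 2: a seed mRNA reaches its miRNAs and, through them,
the competing non-coding partners).

## Enrichment

One-sided over-representation only (the procedure tests enrichment,
not depletion), through the same hypergeometric kernel as the sponge
test. The background defaults to all expressed transcripts of the
relevant class rather than a whole-genome catalogue — the
expression-aware background is standard practice. Raw p < 0.05 selects;
the BH column is always reported. Note the upper-tail p is
non-increasing in the background size B for fixed margins: a fixed
overlap becomes more surprising in a larger background.

## Reporting

Percentages round half-up to match printed two-decimal conventions
(`decimal.Decimal`, not bankers' rounding). Detection percentages are
of the *reference* isoform count, not of all detected isoforms
(verified: 18891/28881 = 65.41%). Every printed percentage recomputes
from its integer numerator and denominator.

## Problem sizes used by the test suite and acceptance script

Recovery statistics average 20 independent simulations at the default
conditions (8 planted triplets each, so n = 160 pair decisions). Null
calibration uses 100 empty simulations at reduced class sizes
(150/40/40/40) — the null property is size-independent while the runs
stay quick — plus 2,000 null transcripts for the Welch type-I rate.
The exact sponge-test oracle enumerates all draws for every universe
size U ≤ 12; the BH oracle covers every multiset of grid p-values up to
length 8.

## Known limitations

- The Welch stand-in does not model count overdispersion; real-data FDR
  behaviour will differ from the simulator's.
- Ortholog projection assumes the map is correct and one-directional
  (cattle → yak); no homology inference is attempted.
- The trans rule and the partner co-expression rule share a threshold
  but not a mechanism; on real data trans calls would require the
  free-energy evidence this package deliberately omits.
- The sponge test treats the target map as ground truth; predictor
  noise propagates directly into x, M and N.
- lncRNA co-DE is rarely observed in practice across species (poor
  lncRNA conservation); the simulator's ortholog copies are more
  optimistic than reality.
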