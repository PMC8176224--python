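"""Synthetic two-species, four-class expression data with planted truth.

The generator emulates the design of a cross-species high-altitude
transcriptome study: three groups (low-altitude cattle ``LAC``,
high-altitude cattle ``HAC``, yak ``LWQY``) with three replicates each,
four RNA classes, a one-to-many cattle-to-yak ortholog map, planted
differential expression of |log2FC| = ``de_log2fc`` in the two
high-altitude groups, and planted ceRNA triplets in which shared
differentially expressed miRNAs multiplicatively repress both partners
(additively on the log2 scale), so that the partners co-vary positively
with each other and negatively with their miRNAs.

The per-sample model on the log2 scale, for transcript t and sample s:

    x_ts = b_t + delta_t * 1[s in high groups] + e_ts,   e ~ N(0, noise_sd)

with b_t ~ N(mu_base, sigma_base), and for a ceRNA partner p with
shared miRNA set S:

    x_ps = b_p - repression_beta * sum_{m in S} (x_ms - b_m) + e_ps.

Abundances are exported as 2**x on a TPM-like linear scale (not
renormalised to 1e6 per sample, which would couple all transcripts).
Yak values are ortholog copies of the cattle values plus N(0,
divergence_sd) log2 noise; the yak matrices carry the LAC and LWQY
sample columns so the low-vs-yak comparison can be computed on yak ids
and then projected back to cattle ids.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cerna import TargetMap
from .enrich import TermMap
from .expression import ExpressionMatrix
from .lncrna import GenomicAnnotation, LncAssocConfig, filter_lncrna_candidates
from .ortholog import OrthologMap

GROUPS = ("LAC", "HAC", "LWQY")      # low-altitude reference first
HIGH_GROUPS = ("HAC", "LWQY")
COMPARISONS = ("LAC_vs_HAC", "LAC_vs_LWQY")

CATTLE_PREFIX = {"mRNA": "BT_MRNA", "lncRNA": "BT_LNC", "miRNA": "BT_MIR", "circRNA": "BT_CIRC"}
YAK_PREFIX = {"mRNA": "BG_MRNA", "lncRNA": "BG_LNC", "miRNA": "BG_MIR", "circRNA": "BG_CIRC"}


@dataclass
class SimulationConfig:
    """All knobs of the simulator; the seed fully determines the outputs."""

    seed: int = 0
    n_groups: int = 3
    replicates_per_group: int = 3
    n_mrna: int = 300
    n_lncrna: int = 80
    n_mirna: int = 120
    n_circrna: int = 80
    frac_de: float = 0.25            # fraction of each class planted DE
    de_log2fc: float = 2.0           # planted |log2FC| in the high groups
    repression_beta: float = 1.5     # per-miRNA log2 repression coefficient
    noise_sd: float = 0.25           # log2-scale residual s.d.
    divergence_sd: float = 0.1       # yak-vs-cattle log2 divergence noise
    n_triplets: int = 8              # planted ceRNA triplets
    min_shared_mirnas: int = 3       # shared miRNAs per planted triplet
    ortholog_multiplicity_max: int = 2
    chrom_length: int = 12_000_000
    frac_shared_de: float = 0.6      # planted DE affecting both high groups
    frac_cis: float = 0.3            # lncRNAs planted within 10 kb of a gene
    frac_antisense: float = 0.2      # lncRNAs overlapping a gene, opposite strand
    cis_gap: int | None = None       # fixed cis gap in bp (random in [1, 10kb] if None)
    frac_lnc_fail_filter: float = 0.1  # lncRNAs failing the >200 nt / >2 exon filter
    decoy_targets_per_mirna: int = 3
    max_private_regulators: int = 2  # extra non-shared miRNAs per partner
    mu_base: float = 5.0             # mean baseline log2 TPM
    sigma_base: float = 1.5

    def __post_init__(self) -> None:
        if self.n_groups != 3:
            raise ValueError("the two-comparison design requires exactly 3 groups")
        if self.replicates_per_group < 2:
            raise ValueError("need >= 2 replicates per group for the DE test")
        for name in ("n_mrna", "n_lncrna", "n_mirna", "n_circrna", "n_triplets"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("frac_de", "frac_shared_de", "frac_cis", "frac_antisense",
                     "frac_lnc_fail_filter"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("de_log2fc", "repression_beta", "noise_sd", "sigma_base"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.divergence_sd < 0:
            raise ValueError("divergence_sd must be >= 0")
        if self.ortholog_multiplicity_max < 1 or self.min_shared_mirnas < 1:
            raise ValueError("ortholog_multiplicity_max and min_shared_mirnas must be >= 1")
        if self.n_triplets:
            if round(self.frac_de * self.n_mrna) < self.n_triplets:
                raise ValueError("frac_de * n_mrna must cover the triplet mRNA partners")
            if round(self.frac_de * self.n_mirna) < self.n_triplets * self.min_shared_mirnas:
                raise ValueError("frac_de * n_mirna must cover the planted shared miRNAs")

    @property
    def class_sizes(self) -> dict[str, int]:
        return {"mRNA": self.n_mrna, "lncRNA": self.n_lncrna,
                "miRNA": self.n_mirna, "circRNA": self.n_circrna}


@dataclass
class TruthSet:
    """Planted ground truth: the oracle for scoring every pipeline stage."""

    de_calls: dict[str, dict[str, str]]          # comparison -> id -> up/down
    triplets: list[tuple[str, str, tuple[str, ...]]]
    ortholog_map_truth: dict[str, frozenset[str]]
    lnc_positional: dict[str, str]               # lncRNA id -> cis/antisense/distal
    class_of: dict[str, str]                     # transcript id -> RNA class

    def co_de(self) -> dict[str, str]:
        """Cattle ids planted DE in both comparisons with one direction."""
        a, b = (self.de_calls.get(c, {}) for c in COMPARISONS)
        return {i: d for i, d in a.items() if b.get(i) == d}

    def co_de_by_class(self, rna_class: str) -> dict[str, str]:
        return {i: d for i, d in self.co_de().items() if self.class_of.get(i) == rna_class}

    def triplet_pairs(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b, _s in self.triplets}


@dataclass
class ExpressionBundle:
    """Everything a pipeline run consumes, in memory."""

    cattle: dict[str, ExpressionMatrix]
    yak: dict[str, ExpressionMatrix]
    ortholog_map: OrthologMap
    targets: TargetMap
    annotation: GenomicAnnotation
    terms: TermMap


def _cattle_ids(rna_class: str, n: int) -> list[str]:
    return [f"{CATTLE_PREFIX[rna_class]}_{i:04d}" for i in range(1, n + 1)]


# --------------------------------------------------------------------------
# annotation
# --------------------------------------------------------------------------

def generate_annotation(config: SimulationConfig) -> GenomicAnnotation:
    """Place genes and lncRNAs on one chromosome with planted positional truth.

    Genes are laid out with 30 kb between consecutive starts of their
    intergenic frames, wide enough that each planted relation is
    unambiguous: cis lncRNAs sit 1..10,000 bp (or ``cis_gap``) downstream
    of their host gene, antisense lncRNAs overlap their host on the
    opposite strand, and distal lncRNAs sit ~14 kb away from everything.
    Truth labels travel in the ``positional_class`` / ``host_gene``
    columns of the feature table.
    """
    rng = np.random.default_rng([config.seed, 0])
    spacing = 30_000
    rows = []
    cursor = 10_000
    gene_ids = _cattle_ids("mRNA", config.n_mrna)
    gene_span: dict[str, tuple[int, int, str]] = {}
    for gid in gene_ids:
        length = int(rng.integers(1_000, 5_001))
        strand = "+" if rng.random() < 0.5 else "-"
        start, end = cursor, cursor + length - 1
        exons = int(rng.integers(3, 10))
        rows.append((gid, "chr1", start, end, strand, "gene", exons, length, "", ""))
        gene_span[gid] = (start, end, strand)
        cursor = end + spacing
    if cursor > config.chrom_length:
        raise ValueError(f"chrom_length={config.chrom_length} cannot hold "
                         f"{config.n_mrna} genes (need ~{cursor} bp)")

    n_lnc = config.n_lncrna
    if n_lnc > config.n_mrna and n_lnc > 0:
        raise ValueError("need at least one host gene per lncRNA (n_lncrna <= n_mrna)")
    n_cis = round(config.frac_cis * n_lnc)
    n_anti = round(config.frac_antisense * n_lnc)
    if n_cis + n_anti > n_lnc:
        n_anti = n_lnc - n_cis
    classes = ["cis"] * n_cis + ["antisense"] * n_anti + ["distal"] * (n_lnc - n_cis - n_anti)
    hosts = rng.choice(config.n_mrna, size=n_lnc, replace=False) if n_lnc else []
    n_fail = round(config.frac_lnc_fail_filter * n_lnc)
    for j, (lid, pos_class) in enumerate(zip(_cattle_ids("lncRNA", n_lnc), classes)):
        host = gene_ids[int(hosts[j])]
        h_start, h_end, h_strand = gene_span[host]
        if j < n_fail:  # fails the candidate filter: too short or too few exons
            length = int(rng.integers(100, 201)) if rng.random() < 0.5 else int(rng.integers(300, 1_001))
            exons = int(rng.integers(1, 3)) if length > 200 else int(rng.integers(3, 6))
        else:
            length = int(rng.integers(300, 2_001))
            exons = int(rng.integers(3, 6))
        if pos_class == "cis":
            gap = int(config.cis_gap if config.cis_gap is not None
                      else rng.integers(1, 10_001))
            start = h_end + gap + 1
            strand = "+" if rng.random() < 0.5 else "-"
        elif pos_class == "antisense":
            offset = int(rng.integers(0, max(1, h_end - h_start - 50)))
            start = h_start + offset
            strand = "-" if h_strand == "+" else "+"
        else:  # distal: > 10 kb from the host and from the next gene
            start = h_end + 14_000
            strand = "+" if rng.random() < 0.5 else "-"
        end = start + length - 1
        rows.append((lid, "chr1", start, end, strand, "lncRNA", exons, length,
                     pos_class, host))

    features = pd.DataFrame(rows, columns=["id", "chrom", "start", "end", "strand",
                                           "kind", "exon_count", "length",
                                           "positional_class", "host_gene"])
    if len(features) and features["end"].max() > config.chrom_length:
        raise ValueError("feature placement exceeds chrom_length")
    return GenomicAnnotation(features)


# --------------------------------------------------------------------------
# expression
# --------------------------------------------------------------------------

def _sample_ids(groups=GROUPS, reps: int = 3) -> list[str]:
    return [f"{g}:{r}" for g in groups for r in range(1, reps + 1)]


def generate_expression(config: SimulationConfig,
                        annotation: GenomicAnnotation) -> tuple[ExpressionBundle, TruthSet]:
    """Draw the full two-species expression bundle plus its ground truth."""
    rng = np.random.default_rng([config.seed, 1])
    reps = config.replicates_per_group
    samples = _sample_ids(GROUPS, reps)
    n_samples = len(samples)
    high_cols = np.array([i for i, s in enumerate(samples)
                          if s.split(":")[0] in HIGH_GROUPS])
    hac_cols = np.array([i for i, s in enumerate(samples) if s.startswith("HAC:")])
    lwqy_cols = np.array([i for i, s in enumerate(samples) if s.startswith("LWQY:")])

    sizes = config.class_sizes
    ids = {c: _cattle_ids(c, n) for c, n in sizes.items()}
    class_of = {i: c for c, lst in ids.items() for i in lst}

    # -- plant DE ids, directions and scopes ---------------------------------
    n_de = {c: round(config.frac_de * n) for c, n in sizes.items()}
    de_ids: dict[str, list[str]] = {}
    lnc_candidates = filter_lncrna_candidates(annotation, LncAssocConfig())
    for c in sizes:
        pool = list(ids[c])
        if c == "lncRNA":
            # prefer candidate-passing lncRNAs so planted partners survive filtering
            passing = [i for i in pool if i in lnc_candidates]
            failing = [i for i in pool if i not in lnc_candidates]
            pool = list(rng.permutation(passing)) + list(rng.permutation(failing))
            de_ids[c] = pool[:n_de[c]]
        else:
            de_ids[c] = list(rng.choice(pool, size=n_de[c], replace=False)) if n_de[c] else []

    direction = {i: (1 if rng.random() < 0.5 else -1)
                 for c in sizes for i in de_ids[c]}
    scope_choices = np.array(["both", "hac", "lwqy"])
    scope_p = [config.frac_shared_de, (1 - config.frac_shared_de) / 2,
               (1 - config.frac_shared_de) / 2]
    scope = {i: str(rng.choice(scope_choices, p=scope_p))
             for c in sizes for i in de_ids[c]}

    # -- plant triplets -------------------------------------------------------
    triplets: list[tuple[str, str, tuple[str, ...]]] = []
    partner_of_triplet: list[tuple[str, str]] = []
    triplet_dir: list[int] = []
    ms = config.min_shared_mirnas
    partner_b_pool = {"lncRNA": [i for i in de_ids["lncRNA"] if i in lnc_candidates],
                      "circRNA": list(de_ids["circRNA"])}
    b_cursor = {"lncRNA": 0, "circRNA": 0}
    for t in range(config.n_triplets):
        a = de_ids["mRNA"][t]
        b_class = "lncRNA" if t % 2 == 0 else "circRNA"
        if b_cursor[b_class] >= len(partner_b_pool[b_class]):
            b_class = "circRNA" if b_class == "lncRNA" else "lncRNA"
        if b_cursor[b_class] >= len(partner_b_pool[b_class]):
            raise ValueError("not enough planted-DE lncRNA/circRNA ids for the triplets; "
                             "raise frac_de or the class sizes")
        b = partner_b_pool[b_class][b_cursor[b_class]]
        b_cursor[b_class] += 1
        shared = tuple(de_ids["miRNA"][t * ms:(t + 1) * ms])
        d = 1 if rng.random() < 0.5 else -1
        for m in shared:
            direction[m], scope[m] = d, "both"
        for p in (a, b):
            scope[p] = "both"
            direction[p] = -d  # repression flips the miRNA direction
        triplets.append((a, b, shared))
        partner_of_triplet.append((a, b))
        triplet_dir.append(d)
    partner_ids = {p for pair in partner_of_triplet for p in pair}

    # -- latent log2 expression ----------------------------------------------
    X: dict[str, np.ndarray] = {}
    base: dict[str, np.ndarray] = {}
    index_of = {c: {i: k for k, i in enumerate(ids[c])} for c in sizes}
    for c in sizes:
        n = sizes[c]
        b = rng.normal(config.mu_base, config.sigma_base, size=n)
        eff = np.zeros((n, n_samples))
        for i in de_ids[c]:
            if i in partner_ids:
                continue  # partners receive their effect through repression
            k = index_of[c][i]
            delta = direction[i] * config.de_log2fc
            if scope[i] in ("both", "hac"):
                eff[k, hac_cols] += delta
            if scope[i] in ("both", "lwqy"):
                eff[k, lwqy_cols] += delta
        noise = rng.normal(0.0, config.noise_sd, size=(n, n_samples))
        X[c] = b[:, None] + eff + noise
        base[c] = b
    for (a, b_id, shared), _d in zip(triplets, triplet_dir):
        dev = np.zeros(n_samples)
        for m in shared:
            km = index_of["miRNA"][m]
            dev += X["miRNA"][km] - base["miRNA"][km]
        for p in (a, b_id):
            cp = class_of[p]
            X[cp][index_of[cp][p]] -= config.repression_beta * dev

    # -- cattle matrices (LAC + HAC columns) ----------------------------------
    cattle_cols = [s for s in samples if not s.startswith("LWQY:")]
    cattle_idx = [samples.index(s) for s in cattle_cols]
    cattle = {}
    for c in sizes:
        tpm = np.power(2.0, X[c][:, cattle_idx])
        cattle[c] = ExpressionMatrix(pd.DataFrame(tpm, index=ids[c], columns=cattle_cols),
                                     species="cattle", rna_class=c)

    # -- ortholog map and yak matrices (LAC + LWQY columns, yak ids) ----------
    yak_cols = [s for s in samples if not s.startswith("HAC:")]
    yak_idx = [samples.index(s) for s in yak_cols]
    pairs: dict[str, set[str]] = {}
    yak = {}
    for c in sizes:
        y_rows, y_ids = [], []
        for i in ids[c]:
            k = index_of[c][i]
            n_copies = int(rng.integers(1, config.ortholog_multiplicity_max + 1))
            yset = set()
            for j in range(1, n_copies + 1):
                yid = f"{YAK_PREFIX[c]}{i[len(CATTLE_PREFIX[c]):]}_{j}"
                div = rng.normal(0.0, config.divergence_sd, size=len(yak_idx)) \
                    if config.divergence_sd else 0.0
                y_rows.append(np.power(2.0, X[c][k, yak_idx] + div))
                y_ids.append(yid)
                yset.add(yid)
            pairs[i] = yset
        data = pd.DataFrame(np.array(y_rows).reshape(len(y_ids), len(yak_cols)),
                            index=y_ids, columns=yak_cols)
        yak[c] = ExpressionMatrix(data, species="yak", rna_class=c)
    omap = OrthologMap(pairs)

    # -- target map ------------------------------------------------------------
    edges: dict[str, dict[str, str]] = {m: {} for m in ids["miRNA"]}
    for (a, b_id, shared), _d in zip(triplets, triplet_dir):
        for m in shared:
            edges[m][a] = class_of[a]
            edges[m][b_id] = class_of[b_id]
    non_de_mirnas = [m for m in ids["miRNA"] if m not in direction]
    for p in partner_ids:
        k = int(rng.integers(0, config.max_private_regulators + 1))
        if k and non_de_mirnas:
            for m in rng.choice(non_de_mirnas, size=min(k, len(non_de_mirnas)),
                                replace=False):
                edges[m][p] = class_of[p]
    all_targets = ids["mRNA"] + ids["lncRNA"] + ids["circRNA"]
    for m in ids["miRNA"]:
        if config.decoy_targets_per_mirna and all_targets:
            for t in rng.choice(all_targets,
                                size=min(config.decoy_targets_per_mirna, len(all_targets)),
                                replace=False):
                edges[m].setdefault(t, class_of[t])
    targets = TargetMap({m: t for m, t in edges.items() if t})

    # -- truth ------------------------------------------------------------------
    de_calls: dict[str, dict[str, str]] = {c: {} for c in COMPARISONS}
    for i, d in direction.items():
        label = "up" if d > 0 else "down"
        if scope[i] in ("both", "hac"):
            de_calls["LAC_vs_HAC"][i] = label
        if scope[i] in ("both", "lwqy"):
            de_calls["LAC_vs_LWQY"][i] = label
    lnc_pos = dict(zip(annotation.of_kind("lncRNA")["id"],
                       annotation.of_kind("lncRNA")["positional_class"])) \
        if "positional_class" in annotation.features.columns else {}
    truth = TruthSet(de_calls=de_calls, triplets=triplets,
                     ortholog_map_truth={c: frozenset(y) for c, y in pairs.items()},
                     lnc_positional=lnc_pos, class_of=class_of)

    terms = _terms_from_truth(truth, ids, rng)
    bundle = ExpressionBundle(cattle=cattle, yak=yak, ortholog_map=omap,
                              targets=targets, annotation=annotation, terms=terms)
    return bundle, truth


def _terms_from_truth(truth: TruthSet, ids: dict[str, list[str]],
                      rng: np.random.Generator) -> TermMap:
    """GMT terms carved from the planted truth (so enrichment is scoreable),
    padded with random mRNA terms as a null reference."""
    co = truth.co_de()
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    partners = sorted({a for a, _b, _s in truth.triplets})
    if partners:
        terms["PLANTED_PARTNER_MRNA"] = ("planted ceRNA mRNA partners", frozenset(partners))
    up = frozenset(i for i, d in co.items() if d == "up" and truth.class_of[i] == "mRNA")
    down = frozenset(i for i, d in co.items() if d == "down" and truth.class_of[i] == "mRNA")
    if up:
        terms["PLANTED_CO_DE_UP"] = ("planted co-DE up-regulated mRNAs", up)
    if down:
        terms["PLANTED_CO_DE_DOWN"] = ("planted co-DE down-regulated mRNAs", down)
    pool = ids["mRNA"]
    for j in range(1, 4):
        if len(pool) >= 15:
            genes = frozenset(rng.choice(pool, size=15, replace=False))
            terms[f"RANDOM_{j}"] = (f"random mRNA set {j}", genes)
    return TermMap(terms)


# --------------------------------------------------------------------------
# fixture I/O
# --------------------------------------------------------------------------

def write_fixture(bundle: ExpressionBundle, truth: TruthSet, directory) -> list[Path]:
    """Write the bundle and truth as plain-text files; lossless round trip.

    Emits per-class TSV matrices for both species, a GTF annotation, the
    ortholog and target maps, a GMT term map, and ``truth.json``.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {directory}: {exc}") from exc
    written: list[Path] = []

    def _write(path: Path, fn) -> None:
        try:
            fn(path)
        except OSError as exc:
            raise OSError(f"failed writing {path}: {exc}") from exc
        written.append(path)

    for species, mats in (("cattle", bundle.cattle), ("yak", bundle.yak)):
        for c, mat in mats.items():
            p = directory / f"expression_{species}_{c}.tsv"
            _write(p, lambda q, m=mat: m.data.rename_axis("transcript_id")
                   .to_csv(q, sep="\t", float_format="%.17g"))
    _write(directory / "annotation.gtf", lambda p: write_gtf(bundle.annotation, p))
    _write(directory / "ortholog_map.tsv", bundle.ortholog_map.to_tsv)
    _write(directory / "target_map.tsv", bundle.targets.to_tsv)
    _write(directory / "terms.gmt", bundle.terms.to_gmt)

    payload = {
        "de_calls": truth.de_calls,
        "triplets": [{"a": a, "b": b, "shared_mirnas": list(s)}
                     for a, b, s in truth.triplets],
        "ortholog_map_truth": {c: sorted(y) for c, y in truth.ortholog_map_truth.items()},
        "lnc_positional": truth.lnc_positional,
        "class_of": truth.class_of,
    }
    _write(directory / "truth.json",
           lambda p: p.write_text(json.dumps(payload, indent=1, sort_keys=True)))
    return written


def read_fixture(directory) -> tuple[ExpressionBundle, TruthSet]:
    """Read back what :func:`write_fixture` wrote."""
    directory = Path(directory)
    cattle, yak = {}, {}
    for species, store in (("cattle", cattle), ("yak", yak)):
        for c in CATTLE_PREFIX:
            p = directory / f"expression_{species}_{c}.tsv"
            if not p.exists():
                raise FileNotFoundError(f"missing expression matrix {p}")
            data = pd.read_csv(p, sep="\t", index_col="transcript_id")
            store[c] = ExpressionMatrix(data, species=species, rna_class=c)
    annotation = read_gtf(directory / "annotation.gtf")
    omap = OrthologMap.from_tsv(directory / "ortholog_map.tsv")
    targets = TargetMap.from_tsv(directory / "target_map.tsv")
    terms = TermMap.from_gmt(directory / "terms.gmt")
    payload = json.loads((directory / "truth.json").read_text())
    truth = TruthSet(
        de_calls=payload["de_calls"],
        triplets=[(t["a"], t["b"], tuple(t["shared_mirnas"]))
                  for t in payload["triplets"]],
        ortholog_map_truth={c: frozenset(y)
                            for c, y in payload["ortholog_map_truth"].items()},
        lnc_positional=payload["lnc_positional"],
        class_of=payload["class_of"],
    )
    bundle = ExpressionBundle(cattle=cattle, yak=yak, ortholog_map=omap,
                              targets=targets, annotation=annotation, terms=terms)
    return bundle, truth


# --------------------------------------------------------------------------
# GTF dialect: gene/transcript/exon features, 1-based inclusive, exons
# partition the transcript span contiguously (length == span)
# --------------------------------------------------------------------------

def write_gtf(annotation: GenomicAnnotation, path) -> None:
    biotype = {"gene": "protein_coding", "lncRNA": "lncRNA"}
    with open(path, "w") as fh:
        for row in annotation.features.itertuples(index=False):
            attrs = (f'gene_id "{row.id}"; transcript_id "{row.id}"; '
                     f'gene_biotype "{biotype[row.kind]}";')
            for feat in ("gene", "transcript"):
                fh.write(f"chr1\tcernapipe\t{feat}\t{row.start}\t{row.end}\t.\t"
                         f"{row.strand}\t.\t{attrs}\n")
            bounds = np.linspace(row.start, row.end + 1, row.exon_count + 1).astype(int)
            for e in range(row.exon_count):
                fh.write(f"chr1\tcernapipe\texon\t{bounds[e]}\t{bounds[e + 1] - 1}\t.\t"
                         f"{row.strand}\t.\t{attrs} exon_number \"{e + 1}\";\n")


def _gtf_attr(attrs: str, key: str) -> str | None:
    for part in attrs.strip().split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part.split(" ", 1)[1].strip('"')
    return None


def read_gtf(path) -> GenomicAnnotation:
    """Minimal reader for the package's own GTF dialect (and for any GTF
    carrying gene_id/transcript_id/gene_biotype attributes)."""
    transcripts: dict[str, dict] = {}
    exon_counts: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GTF line in {path}: {line!r}")
            chrom, _src, feat, start, end, _score, strand, _frame, attrs = fields
            tid = _gtf_attr(attrs, "transcript_id") or _gtf_attr(attrs, "gene_id")
            if tid is None:
                continue
            if feat == "transcript":
                bio = _gtf_attr(attrs, "gene_biotype") or "protein_coding"
                transcripts[tid] = {
                    "id": tid, "chrom": chrom, "start": int(start), "end": int(end),
                    "strand": strand,
                    "kind": "lncRNA" if bio == "lncRNA" else "gene",
                }
            elif feat == "exon":
                exon_counts[tid] = exon_counts.get(tid, 0) + 1
    rows = []
    for tid, rec in transcripts.items():
        rec["exon_count"] = exon_counts.get(tid, 1)
        rec["length"] = rec["end"] - rec["start"] + 1
        rows.append(rec)
    features = pd.DataFrame(rows, columns=["id", "chrom", "start", "end", "strand",
                                           "kind", "exon_count", "length"])
    return GenomicAnnotation(features)


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
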