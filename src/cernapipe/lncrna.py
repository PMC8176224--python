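"""lncRNA candidate filtering and lncRNA–gene association rules.

Candidates must be longer than 200 nt with more than two exons (both
strict, as specified).  Associations are assigned with precedence
antisense > cis > trans:

* **antisense** — >= 1 bp genomic overlap with a gene on the opposite
  strand (evidence: overlap length in bp);
* **cis** — non-overlapping, same chromosome, gap <= 10 kb up- or
  downstream (inclusive at exactly 10 kb; evidence: gap in bp);
* **trans** — position-independent co-expression, Pearson r > 0.9 on
  log2(TPM+1) across shared samples (evidence: r).

Coordinates are 1-based inclusive (GTF convention); the gap is the
number of bases strictly between two intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

ASSOC_COLUMNS = ["lncrna_id", "gene_id", "relation", "evidence"]


@dataclass
class GenomicAnnotation:
    """Strand-annotated gene and lncRNA intervals.

    ``features`` columns: id, chrom, start, end, strand, kind
    ({gene, lncRNA}), exon_count, length (nt).  Coordinates are 1-based
    inclusive.
    """

    features: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.features
        required = {"id", "chrom", "start", "end", "strand", "kind", "exon_count", "length"}
        missing = required - set(f.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if f["id"].duplicated().any():
            raise ValueError("duplicate feature ids in annotation")
        if len(f):
            if (f["start"] > f["end"]).any():
                raise ValueError("feature with start > end")
            if (f["exon_count"] < 1).any():
                raise ValueError("feature with exon_count < 1")
            bad = set(f["kind"]) - {"gene", "lncRNA"}
            if bad:
                raise ValueError(f"unknown feature kinds: {bad}")

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.features[self.features["kind"] == kind]


@dataclass
class LncAssocConfig:
    cis_window: int = 10_000
    min_length: int = 200   # strict >
    min_exons: int = 2      # strict >
    trans_pcc_min: float = 0.9

    def __post_init__(self) -> None:
        if self.cis_window <= 0:
            raise ValueError("cis_window must be positive")


def filter_lncrna_candidates(annotation: GenomicAnnotation,
                             config: LncAssocConfig | None = None) -> set[str]:
    """lncRNA ids with length > min_length and exon_count > min_exons."""
    config = config or LncAssocConfig()
    lnc = annotation.of_kind("lncRNA")
    keep = lnc[(lnc["length"] > config.min_length) & (lnc["exon_count"] > config.min_exons)]
    return set(keep["id"])


def _pairwise(lnc: pd.DataFrame, genes: pd.DataFrame):
    """Vectorised all-pairs interval geometry per chromosome.

    Yields (lnc_row, gene_rows, gap, overlap) blocks where gap is bases
    strictly between the intervals (0 when touching or overlapping) and
    overlap is shared bases (0 when disjoint), both inclusive-coordinate.
    """
    for chrom, lsub in lnc.groupby("chrom", sort=True):
        gsub = genes[genes["chrom"] == chrom]
        if gsub.empty:
            continue
        ls, le = lsub["start"].to_numpy()[:, None], lsub["end"].to_numpy()[:, None]
        gs, ge = gsub["start"].to_numpy()[None, :], gsub["end"].to_numpy()[None, :]
        overlap = np.maximum(0, np.minimum(le, ge) - np.maximum(ls, gs) + 1)
        gap = np.maximum(0, np.maximum(ls, gs) - np.minimum(le, ge) - 1)
        yield lsub, gsub, gap, overlap


def classify_cis(annotation: GenomicAnnotation,
                 config: LncAssocConfig | None = None) -> pd.DataFrame:
    """Cis associations: same chromosome, no overlap, gap <= cis_window.

    Strand-agnostic; evidence is the gap distance in bp.
    """
    config = config or LncAssocConfig()
    rows = []
    for lsub, gsub, gap, overlap in _pairwise(annotation.of_kind("lncRNA"),
                                              annotation.of_kind("gene")):
        hit = (overlap == 0) & (gap <= config.cis_window)
        li, gi = np.nonzero(hit)
        for a, b in zip(li, gi):
            rows.append((lsub["id"].iat[a], gsub["id"].iat[b], "cis", float(gap[a, b])))
    return _assoc_frame(rows)


def classify_antisense(annotation: GenomicAnnotation) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Antisense associations (opposite-strand overlap >= 1 bp).

    Returns ``(antisense, sense_overlaps)``; same-strand overlaps are
    reported in the second frame and are not antisense candidates.
    Evidence is the overlap length in bp.
    """
    anti_rows, sense_rows = [], []
    for lsub, gsub, _gap, overlap in _pairwise(annotation.of_kind("lncRNA"),
                                               annotation.of_kind("gene")):
        opposite = lsub["strand"].to_numpy()[:, None] != gsub["strand"].to_numpy()[None, :]
        li, gi = np.nonzero(overlap >= 1)
        for a, b in zip(li, gi):
            row = (lsub["id"].iat[a], gsub["id"].iat[b], "antisense", float(overlap[a, b]))
            (anti_rows if opposite[a, b] else sense_rows).append(row)
    sense = _assoc_frame([(l, g, "sense_overlap", e) for l, g, _r, e in sense_rows])
    return _assoc_frame(anti_rows), sense


def classify_trans(lnc_expr: ExpressionMatrix, mrna_expr: ExpressionMatrix,
                   config: LncAssocConfig | None = None,
                   exclude_pairs: set[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Trans associations: Pearson r > trans_pcc_min on log2(TPM+1).

    ``exclude_pairs`` (lncrna_id, gene_id) removes pairs already
    explained positionally (cis or antisense).
    """
    config = config or LncAssocConfig()
    exclude_pairs = exclude_pairs or set()
    if list(lnc_expr.sample_ids) != list(mrna_expr.sample_ids):
        raise ValueError("lncRNA and mRNA matrices must share the same sample universe")
    L = lnc_expr.log2().to_numpy()
    M = mrna_expr.log2().to_numpy()
    r = _cross_corr(L, M)
    rows = []
    li, gi = np.nonzero(r > config.trans_pcc_min)
    lnc_ids, gene_ids = lnc_expr.transcript_ids, mrna_expr.transcript_ids
    for a, b in zip(li, gi):
        pair = (lnc_ids[a], gene_ids[b])
        if pair in exclude_pairs:
            continue
        rows.append((pair[0], pair[1], "trans", float(r[a, b])))
    return _assoc_frame(rows)


def associate(annotation: GenomicAnnotation, lnc_expr: ExpressionMatrix | None = None,
              mrna_expr: ExpressionMatrix | None = None,
              config: LncAssocConfig | None = None) -> pd.DataFrame:
    """All associations with precedence antisense > cis > trans.

    A (lncRNA, gene) pair carries exactly one relation: antisense
    overlap wins over a cis call, and positional relations win over
    trans co-expression.  Trans is only computed when both expression
    matrices are supplied.
    """
    config = config or LncAssocConfig()
    anti, _sense = classify_antisense(annotation)
    cis = classify_cis(annotation, config)
    anti_pairs = set(zip(anti["lncrna_id"], anti["gene_id"]))
    keep = np.array([p not in anti_pairs
                     for p in zip(cis["lncrna_id"], cis["gene_id"])], dtype=bool)
    cis = cis.loc[keep] if len(cis) else cis
    frames = [anti, cis]
    if lnc_expr is not None and mrna_expr is not None:
        taken = anti_pairs | set(zip(cis["lncrna_id"], cis["gene_id"]))
        frames.append(classify_trans(lnc_expr, mrna_expr, config, exclude_pairs=taken))
    nonempty = [f for f in frames if len(f)]
    positional = pd.concat(nonempty, ignore_index=True) if nonempty else _assoc_frame([])
    return positional.sort_values(["lncrna_id", "gene_id"]).reset_index(drop=True)


def _cross_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-by-row Pearson correlation matrix between A and B (constant rows -> nan)."""
    def standardize(X):
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = (X - mu) / sd
        Z[~np.isfinite(Z)] = np.nan
        return Z
    Za, Zb = standardize(A), standardize(B)
    with np.errstate(invalid="ignore"):
        return Za @ Zb.T / A.shape[1]


def _assoc_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=ASSOC_COLUMNS)


def write_associations(assoc: pd.DataFrame, path) -> None:
    assoc.to_csv(path, sep="\t", index=False, float_format="%.17g")
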