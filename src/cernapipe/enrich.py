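"""Over-representation analysis against GMT-style term -> gene maps.

One-sided Fisher exact test per term: with k study hits in a term of
size K, a study of size n, and a background of size B, the p-value is
the hypergeometric upper tail P(X >= k) — the same kernel as the ceRNA
sponge test, called on (x=k, U=B, M=K, N=n).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cerna import sponge_test
from .de import benjamini_hochberg

ENRICH_COLUMNS = ["term_id", "description", "k", "K", "n", "B", "p", "fdr", "significant"]


@dataclass
class TermMap:
    """term id -> (description, gene id set)."""

    terms: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        self.terms = {t: (d, frozenset(g)) for t, (d, g) in self.terms.items()}
        empty = [t for t, (_d, g) in self.terms.items() if not g]
        if empty:
            raise ValueError(f"terms with empty gene sets: {empty[:5]}")

    @classmethod
    def from_gmt(cls, path) -> "TermMap":
        terms = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"malformed GMT line (need term, description, genes): {line!r}")
                terms[fields[0]] = (fields[1], frozenset(fields[2:]))
        return cls(terms)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for term in sorted(self.terms):
                desc, genes = self.terms[term]
                fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def fisher_enrichment(study, background, terms: TermMap,
                      p_max: float = 0.05) -> pd.DataFrame:
    """Per-term over-representation table, sorted by p then term id.

    ``study`` must be a subset of ``background``; term gene sets are
    intersected with the background before testing.  Rows carry the
    2x2-table margins, the one-sided Fisher p, and its BH adjustment;
    ``significant`` flags raw p < p_max.
    """
    study, background = set(study), set(background)
    offenders = sorted(study - background)
    if offenders:
        raise ValueError(f"study genes outside the background: {offenders[:10]}")
    n, B = len(study), len(background)
    rows = []
    for term in sorted(terms.terms):
        desc, genes = terms.terms[term]
        genes = genes & background
        if not genes:
            continue
        k, K = len(genes & study), len(genes)
        p = sponge_test(k, B, K, n)
        rows.append((term, desc, k, K, n, B, p))
    out = pd.DataFrame(rows, columns=ENRICH_COLUMNS[:7])
    out["fdr"] = benjamini_hochberg(out["p"].to_numpy()) if len(out) else pd.Series(dtype=float)
    out["significant"] = out["p"] < p_max
    return out.sort_values(["p", "term_id"]).reset_index(drop=True)


def write_enrichment(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")
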