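"""Summary arithmetic and the plain-text pipeline report.

Detection summaries follow the study's table convention: the percentage
is of the *reference* isoform count, not of all detected isoforms, and
percentages are printed with half-up rounding (two decimals for
detection rates, whole percent for expression ratios).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .ortholog import CoDESet, direction_tally


def _round_half_up(value: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class DetectionSummary:
    group: str
    known_count: int
    novel_count: int
    all_count: int
    reference_count: int
    known_pct: float  # 100 * known / reference, half-up to 2 decimals


def detection_summary(known: int, novel: int, reference: int,
                      group: str = "") -> DetectionSummary:
    """Known/novel isoform detection summary for one group."""
    if reference == 0:
        raise ValueError("reference isoform count must be nonzero")
    if not reference >= known >= 0 or novel < 0:
        raise ValueError(f"need reference >= known >= 0 and novel >= 0, "
                         f"got known={known}, novel={novel}, reference={reference}")
    pct = _round_half_up(100.0 * known / reference, 2)
    return DetectionSummary(group=group, known_count=known, novel_count=novel,
                            all_count=known + novel, reference_count=reference,
                            known_pct=pct)


def expression_ratio(novel_mean: float, known_mean: float) -> int:
    """Novel-to-known mean expression, as a whole percent (half-up)."""
    if known_mean <= 0:
        raise ValueError("known mean expression must be positive")
    return int(_round_half_up(100.0 * novel_mean / known_mean, 0))


def run_report(detection: list[DetectionSummary] | None = None,
               de_tables: dict[str, pd.DataFrame] | None = None,
               co_de_sets: dict[str, CoDESet] | None = None,
               network=None,
               enrichment: pd.DataFrame | None = None) -> str:
    """Deterministic plain-text report over whatever stages ran.

    Sections: detection summaries, per-comparison direction tallies,
    co-DE Venn counts, network composition, and significant enrichment
    terms.  Absent stages produce zero-count sections.
    """
    lines = ["# pipeline report", ""]

    lines.append("## detection")
    for d in sorted(detection or [], key=lambda d: d.group):
        lines.append(f"{d.group}\tknown={d.known_count}({d.known_pct:.2f}%)\t"
                     f"novel={d.novel_count}\tall={d.all_count}\treference={d.reference_count}")
    if not detection:
        lines.append("(none)")
    lines.append("")

    lines.append("## differential expression")
    for name in sorted(de_tables or {}):
        up, down, total = direction_tally(de_tables[name])
        lines.append(f"{name}\tup={up}\tdown={down}\ttotal={total}")
    if not de_tables:
        lines.append("(none)\tup=0\tdown=0\ttotal=0")
    lines.append("")

    lines.append("## co-differential expression")
    for name in sorted(co_de_sets or {}):
        codes = co_de_sets[name]
        up, down, total = direction_tally(codes)
        only1, only2, shared = codes.venn
        lines.append(f"{name}\tvenn=({only1},{only2},{shared})\tup={up}\tdown={down}\t"
                     f"total={total}\tconflicts={len(codes.conflicts)}")
    if not co_de_sets:
        lines.append("(none)\tvenn=(0,0,0)\tup=0\tdown=0\ttotal=0\tconflicts=0")
    lines.append("")

    lines.append("## ceRNA network")
    if network is not None and network.graph.number_of_nodes():
        by_class: dict[str, int] = {}
        for _n, d in network.graph.nodes(data=True):
            by_class[d["class"]] = by_class.get(d["class"], 0) + 1
        classes = "\t".join(f"{k}={by_class[k]}" for k in sorted(by_class))
        n_pair = len(network.cerna_edges)
        n_tgt = network.graph.number_of_edges() - n_pair
        lines.append(f"nodes={network.graph.number_of_nodes()}\t{classes}")
        lines.append(f"edges={network.graph.number_of_edges()}\t"
                     f"cerna_pair={n_pair}\tmirna_target={n_tgt}")
    else:
        lines.append("nodes=0")
        lines.append("edges=0\tcerna_pair=0\tmirna_target=0")
    lines.append("")

    lines.append("## enrichment")
    if enrichment is not None and len(enrichment):
        sig = enrichment[enrichment["significant"]]
        lines.append(f"terms_tested={len(enrichment)}\tsignificant={len(sig)}")
        for row in sig.itertuples(index=False):
            lines.append(f"{row.term_id}\tk={row.k}/K={row.K}\tp={row.p:.4g}\tfdr={row.fdr:.4g}")
    else:
        lines.append("terms_tested=0\tsignificant=0")
    lines.append("")

    return "\n".join(lines)
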