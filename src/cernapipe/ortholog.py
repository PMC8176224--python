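"""Ortholog projection and co-differential intersection.

Yak DE results are projected onto cattle identifiers through a
one-to-many ortholog map (one cattle id may correspond to several yak
ids), and the two comparisons are intersected into a co-differentially
expressed set keyed on cattle ids, with a Venn summary and explicit
handling of direction conflicts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .de import DE_COLUMNS

log = logging.getLogger(__name__)


@dataclass
class OrthologMap:
    """cattle id -> non-empty set of yak ids; each yak id maps back uniquely."""

    pairs: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.pairs = {c: frozenset(y) for c, y in self.pairs.items()}
        seen: dict[str, str] = {}
        for cattle, yaks in self.pairs.items():
            if not yaks:
                raise ValueError(f"cattle id {cattle!r} maps to an empty yak set")
            for y in yaks:
                if y in seen:
                    raise ValueError(f"yak id {y!r} mapped under both {seen[y]!r} and {cattle!r}")
                seen[y] = cattle
        self._cattle_of = seen

    def cattle_of(self, yak_id: str) -> str | None:
        return self._cattle_of.get(yak_id)

    @classmethod
    def from_tsv(cls, path) -> "OrthologMap":
        pairs: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cattle, yak = line.split("\t")
                pairs.setdefault(cattle, set()).add(yak)
        return cls(pairs)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for cattle in sorted(self.pairs):
                for yak in sorted(self.pairs[cattle]):
                    fh.write(f"{cattle}\t{yak}\n")


@dataclass
class CoDESet:
    """Direction-consistent intersection of two DE tables.

    ``ids`` are significant in both comparisons with the same direction;
    ``conflicts`` are significant in both but with opposite directions
    (excluded from ``ids`` but kept for reporting).  ``venn`` counts
    significant ids: (only comparison 1, only comparison 2, shared before
    conflict filtering).
    """

    ids: set[str] = field(default_factory=set)
    direction_of: dict[str, str] = field(default_factory=dict)
    conflicts: set[str] = field(default_factory=set)
    venn: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        if self.ids & self.conflicts:
            raise ValueError("co-DE ids and conflicts must be disjoint")

    def to_frame(self) -> pd.DataFrame:
        rows = [(i, self.direction_of[i]) for i in sorted(self.ids)]
        rows += [(i, "conflict") for i in sorted(self.conflicts)]
        return pd.DataFrame(rows, columns=["transcript_id", "direction"]).set_index("transcript_id")


def project_to_cattle(yak_de: pd.DataFrame, omap: OrthologMap,
                      aggregation: str = "any") -> pd.DataFrame:
    """Re-key a yak DE table by cattle id through the ortholog map.

    A cattle id is significant iff >= 1 mapped yak transcript is
    significant (``aggregation="any"``, default) or iff all are
    (``aggregation="all"``).  Direction is the unanimous direction of
    the significant mapped transcripts; disagreement yields direction
    ``"conflict"``.  Expression summaries are means over the mapped yak
    transcripts; p and fdr are the minima (most significant mapped
    transcript).  Unmapped yak ids are counted in ``result.attrs["n_unmapped"]``.
    """
    if aggregation not in ("any", "all"):
        raise ValueError("aggregation must be 'any' or 'all'")
    groups: dict[str, list[str]] = {}
    n_unmapped = 0
    for yak_id in yak_de.index:
        cattle = omap.cattle_of(yak_id)
        if cattle is None:
            n_unmapped += 1
            continue
        groups.setdefault(cattle, []).append(yak_id)
    if n_unmapped:
        log.info("project_to_cattle: %d yak transcripts had no ortholog", n_unmapped)
    rows = []
    for cattle in sorted(groups):
        sub = yak_de.loc[groups[cattle]]
        sig = sub[sub["significant"]]
        significant = bool(len(sig)) if aggregation == "any" else bool(len(sig) == len(sub))
        if significant and len(sig):
            dirs = set(sig["direction"])
            direction = dirs.pop() if len(dirs) == 1 else "conflict"
        else:
            direction = "none"
        rows.append((cattle, sub["mean_a"].mean(), sub["mean_b"].mean(),
                     sub["log2fc"].mean(), sub["p"].min(), sub["fdr"].min(),
                     direction, significant))
    out = pd.DataFrame(rows, columns=["transcript_id"] + DE_COLUMNS).set_index("transcript_id")
    out.attrs["n_unmapped"] = n_unmapped
    return out


def co_differential(de_1: pd.DataFrame, de_2: pd.DataFrame,
                    require_direction_agreement: bool = True) -> CoDESet:
    """Intersect two DE tables (same id namespace) into a CoDESet.

    With ``require_direction_agreement`` (default) jointly significant
    ids whose directions disagree are reported in ``conflicts`` rather
    than in ``ids``; with the flag off they are admitted under the
    direction from ``de_1``.
    """
    sig1 = _significant_directions(de_1)
    sig2 = _significant_directions(de_2)
    if sig1 and sig2 and not (set(sig1) & set(sig2)):
        log.warning("co_differential: significant sets share no ids; "
                    "are the tables keyed on the same namespace?")
    shared = set(sig1) & set(sig2)
    ids, conflicts, direction_of = set(), set(), {}
    for i in shared:
        agree = sig1[i] == sig2[i] and sig1[i] in ("up", "down")
        if agree or not require_direction_agreement:
            ids.add(i)
            direction_of[i] = sig1[i]
        else:
            conflicts.add(i)
    venn = (len(sig1) - len(shared), len(sig2) - len(shared), len(shared))
    return CoDESet(ids=ids, direction_of=direction_of, conflicts=conflicts, venn=venn)


def _significant_directions(de: pd.DataFrame) -> dict[str, str]:
    sig = de[de["significant"]]
    return dict(zip(sig.index, sig["direction"]))


def direction_tally(obj) -> tuple[int, int, int]:
    """(n_up, n_down, n_total) over the significant entries of a DE table
    or the retained ids of a CoDESet; conflicts are not tallied."""
    if isinstance(obj, CoDESet):
        dirs = list(obj.direction_of.values())
    else:
        dirs = list(obj.loc[obj["significant"], "direction"])
    n_up = sum(d == "up" for d in dirs)
    n_down = sum(d == "down" for d in dirs)
    return n_up, n_down, n_up + n_down
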