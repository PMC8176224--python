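"""Expression matrix container.

A single in-memory representation is used across the whole pipeline: a
transcripts-by-samples table of TPM-like abundances, with each sample
assigned to an experimental group (e.g. ``LAC``, ``HAC``, ``LWQY``), and
the matrix tagged with the species and RNA class it quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RNA_CLASSES = ("mRNA", "lncRNA", "miRNA", "circRNA")

#: sample identifiers encode their group as ``group:replicate``
SAMPLE_SEP = ":"


def group_of_sample(sample_id: str) -> str:
    """Extract the group label from a ``group:replicate`` sample id."""
    if SAMPLE_SEP not in sample_id:
        raise ValueError(f"sample id {sample_id!r} does not encode a group (expected 'group:replicate')")
    return sample_id.split(SAMPLE_SEP, 1)[0]


@dataclass
class ExpressionMatrix:
    """TPM abundance table for one RNA class in one species.

    Parameters
    ----------
    data
        DataFrame indexed by transcript id with one column per sample;
        values are non-negative TPM-like abundances.
    species
        Species label, e.g. ``"cattle"`` or ``"yak"``.
    rna_class
        One of ``mRNA``, ``lncRNA``, ``miRNA``, ``circRNA``.
    group_of
        Sample id -> group label. Derived from the ``group:replicate``
        column naming when omitted.
    """

    data: pd.DataFrame
    species: str
    rna_class: str
    group_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(f"unknown RNA class {self.rna_class!r}; expected one of {RNA_CLASSES}")
        if self.data.index.name is None:
            self.data = self.data.rename_axis("transcript_id")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate transcript ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if not self.group_of:
            self.group_of = {s: group_of_sample(s) for s in self.data.columns}
        missing = [s for s in self.data.columns if s not in self.group_of]
        if missing:
            raise ValueError(f"samples without a group assignment: {missing}")
        vals = self.data.to_numpy()
        if vals.size and (not np.isfinite(vals).all() or (vals < 0).any()):
            raise ValueError("expression values must be finite and non-negative")

    # -- convenience accessors -------------------------------------------------

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.data.columns:
            seen.setdefault(self.group_of[s], None)
        return list(seen)

    def samples_in_group(self, group: str) -> list[str]:
        cols = [s for s in self.data.columns if self.group_of[s] == group]
        if not cols:
            raise KeyError(f"group {group!r} not present in matrix "
                           f"({self.species}/{self.rna_class}; groups: {self.groups})")
        return cols

    def subset(self, transcript_ids) -> "ExpressionMatrix":
        """Restrict the matrix to the given transcripts (order preserved)."""
        keep = [t for t in self.data.index if t in set(transcript_ids)]
        return ExpressionMatrix(self.data.loc[keep], self.species, self.rna_class,
                                dict(self.group_of))

    def subset_groups(self, groups) -> "ExpressionMatrix":
        cols = [s for s in self.data.columns if self.group_of[s] in set(groups)]
        return ExpressionMatrix(self.data[cols], self.species, self.rna_class,
                                {s: self.group_of[s] for s in cols})

    def log2(self, pseudocount: float = 1.0) -> pd.DataFrame:
        """log2(TPM + pseudocount) view of the data."""
        return np.log2(self.data + pseudocount)
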