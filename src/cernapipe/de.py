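"""Differential expression with class-specific significance criteria.

Fold changes are computed on pseudocounted TPM means; significance comes
from a Welch unequal-variance t-test on log2(TPM + pseudocount) with a
variance floor so that zero-variance groups remain testable.  mRNA and
lncRNA are called at BH-adjusted FDR < 0.05 together with |log2FC| >= 1,
while miRNA and circRNA are called at raw P < 0.05 with the same fold-
change gate — the class-specific convention of the study design this
pipeline models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st

from .expression import ExpressionMatrix

#: per-class significance criterion: "fdr" (BH-adjusted) or "p" (raw)
DEFAULT_CRITERIA = {"mRNA": "fdr", "lncRNA": "fdr", "miRNA": "p", "circRNA": "p"}

DE_COLUMNS = ["mean_a", "mean_b", "log2fc", "p", "fdr", "direction", "significant"]


@dataclass
class DEConfig:
    log2fc_min: float = 1.0
    fdr_max: float = 0.05
    p_max: float = 0.05
    pseudocount: float = 1.0
    variance_floor: float = 1e-8
    criterion_of_class: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CRITERIA))

    def __post_init__(self) -> None:
        if self.log2fc_min <= 0:
            raise ValueError("log2fc_min must be positive")
        for name in ("fdr_max", "p_max"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.pseudocount <= 0 or self.variance_floor <= 0:
            raise ValueError("pseudocount and variance_floor must be positive")
        bad = {c for c in self.criterion_of_class.values()} - {"fdr", "p"}
        if bad:
            raise ValueError(f"unknown criteria {bad}; use 'fdr' or 'p'")


def log2_fold_change(matrix: ExpressionMatrix, group_a: str, group_b: str,
                     pseudocount: float = 1.0) -> pd.Series:
    """log2((mean_b + pc) / (mean_a + pc)) per transcript (b relative to a)."""
    a = matrix.data[matrix.samples_in_group(group_a)].mean(axis=1)
    b = matrix.data[matrix.samples_in_group(group_b)].mean(axis=1)
    return np.log2((b + pseudocount) / (a + pseudocount)).rename("log2fc")


def de_test(matrix: ExpressionMatrix, group_a: str, group_b: str,
            pseudocount: float = 1.0, variance_floor: float = 1e-8) -> pd.Series:
    """Two-sided Welch t-test on log2(TPM + pseudocount), per transcript.

    Per-group variances are floored at ``variance_floor``; identical
    samples in both groups therefore give t = 0 and p = 1.  Returns
    p-values in (0, 1].
    """
    cols_a = matrix.samples_in_group(group_a)
    cols_b = matrix.samples_in_group(group_b)
    for grp, cols in ((group_a, cols_a), (group_b, cols_b)):
        if len(cols) < 2:
            raise ValueError(f"group {grp!r} has {len(cols)} sample(s); Welch test needs >= 2")
    log = matrix.log2(pseudocount)
    xa = log[cols_a].to_numpy()
    xb = log[cols_b].to_numpy()
    na, nb = xa.shape[1], xb.shape[1]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va = np.maximum(xa.var(axis=1, ddof=1), variance_floor)
    vb = np.maximum(xb.var(axis=1, ddof=1), variance_floor)
    se2 = va / na + vb / nb
    t = (mb - ma) / np.sqrt(se2)
    # Welch–Satterthwaite degrees of freedom
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * _st.t.sf(np.abs(t), df)
    return pd.Series(np.minimum(p, 1.0), index=matrix.data.index, name="p")


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, in input order.

    q_(i) = min_{j >= i} (p_(j) * m / j), capped at 1, where p_(1..m) are
    the sorted p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d sequence of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def call_de(matrix: ExpressionMatrix, group_a: str, group_b: str,
            config: DEConfig | None = None) -> pd.DataFrame:
    """Full DE table for one comparison (``group_b`` relative to ``group_a``).

    Returns a DataFrame indexed by transcript id (sorted) with columns
    ``mean_a, mean_b, log2fc, p, fdr, direction, significant``.  The BH
    adjustment is computed within this matrix only, so the FDR is per
    comparison per RNA class.
    """
    config = config or DEConfig()
    crit = config.criterion_of_class.get(matrix.rna_class)
    if crit is None:
        raise ValueError(f"no significance criterion configured for class {matrix.rna_class!r}")
    mean_a = matrix.data[matrix.samples_in_group(group_a)].mean(axis=1)
    mean_b = matrix.data[matrix.samples_in_group(group_b)].mean(axis=1)
    lfc = log2_fold_change(matrix, group_a, group_b, config.pseudocount)
    p = de_test(matrix, group_a, group_b, config.pseudocount, config.variance_floor)
    fdr = pd.Series(benjamini_hochberg(p.to_numpy()), index=p.index, name="fdr")
    stat_ok = fdr < config.fdr_max if crit == "fdr" else p < config.p_max
    significant = (np.abs(lfc) >= config.log2fc_min) & stat_ok
    direction = np.where(~significant, "none", np.where(lfc > 0, "up", "down"))
    table = pd.DataFrame({
        "mean_a": mean_a, "mean_b": mean_b, "log2fc": lfc,
        "p": p, "fdr": fdr, "direction": direction, "significant": significant,
    })
    table.index.name = "transcript_id"
    return table.sort_index()


def write_de_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", float_format="%.17g")


def read_de_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col="transcript_id")
    table["significant"] = table["significant"].astype(bool)
    return table
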