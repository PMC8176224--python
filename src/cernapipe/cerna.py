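"""Competing-endogenous-RNA (ceRNA) network inference.

A candidate ceRNA pair (a, b) enters the network iff

1. both partners are co-differentially expressed,
2. their Pearson correlation on log2(TPM+1) exceeds ``pcc_min`` (> 0.9),
3. both are retained targets (Spearman rho < ``scc_max`` = -0.7 with the
   miRNA, on TPM) of at least one common miRNA, and
4. the hypergeometric sponge test on the number of shared regulator
   miRNAs is significant at ``sponge_p_max`` (< 0.05).

The sponge test: for a pair (A, B) with regulator miRNA sets C (|C| = M)
and D (|D| = N) out of a universe of U identified miRNAs sharing x
miRNAs, p = P(X >= x) where X is hypergeometric — the upper tail
1 - F(x - 1; U, M, N), computed in exact integer arithmetic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as _st

from .expression import ExpressionMatrix
from .ortholog import CoDESet

log = logging.getLogger(__name__)

SPONGE_COLUMNS = ["gene_a", "gene_b", "class_a", "class_b", "x", "M", "N", "U", "p",
                  "pcc", "shared_mirnas"]

#: partner class pairs assembled by default: lncRNA–mRNA and circRNA–mRNA
DEFAULT_PAIR_CLASSES = frozenset({frozenset({"mRNA", "lncRNA"}), frozenset({"mRNA", "circRNA"})})


@dataclass
class TargetMap:
    """miRNA id -> {target id: target class}; no self-targets."""

    edges: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        for mirna, targets in self.edges.items():
            if mirna in targets:
                raise ValueError(f"self-target for {mirna!r}")

    def regulators_of(self, target_id: str) -> set[str]:
        return {m for m, t in self.edges.items() if target_id in t}

    def targets_long(self) -> pd.DataFrame:
        rows = [(m, t, c) for m, targets in self.edges.items() for t, c in targets.items()]
        return pd.DataFrame(rows, columns=["mirna_id", "target_id", "target_class"])

    @classmethod
    def from_tsv(cls, path) -> "TargetMap":
        edges: dict[str, dict[str, str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                mirna, target, klass = line.split("\t")
                edges.setdefault(mirna, {})[target] = klass
        return cls(edges)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for mirna in sorted(self.edges):
                for target in sorted(self.edges[mirna]):
                    fh.write(f"{mirna}\t{target}\t{self.edges[mirna][target]}\n")


@dataclass
class CernaConfig:
    scc_max: float = -0.7          # strict <
    pcc_min: float = 0.9           # strict >
    sponge_p_max: float = 0.05     # strict <
    universe_size: int | None = None  # default: number of miRNAs in the expression universe
    tail: str = "at_least"         # "at_least" = P(X >= x); "above" = P(X > x)
    bh_correct: bool = False       # select on BH-adjusted sponge p instead of raw
    require_co_de: bool = True     # partners must be co-DE (vs DE in either comparison)
    pair_classes: frozenset = DEFAULT_PAIR_CLASSES
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not -1 <= self.scc_max < 0:
            raise ValueError("scc_max must lie in [-1, 0)")
        if not 0 < self.pcc_min <= 1:
            raise ValueError("pcc_min must lie in (0, 1]")
        if not 0 < self.sponge_p_max <= 1:
            raise ValueError("sponge_p_max must lie in (0, 1]")
        if self.tail not in ("at_least", "above"):
            raise ValueError("tail must be 'at_least' or 'above'")


# --------------------------------------------------------------------------
# correlation kernels
# --------------------------------------------------------------------------

def pearson_r(x, y) -> float:
    """Product-moment correlation; nan for constant input (undefined)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-d vectors with >= 3 points")
    dx, dy = x - x.mean(), y - y.mean()
    sx, sy = np.sqrt((dx * dx).sum()), np.sqrt((dy * dy).sum())
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.clip((dx * dy).sum() / (sx * sy), -1.0, 1.0))


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson on average ranks (ties share the
    mean rank); nan for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-d vectors with >= 3 points")
    return pearson_r(_st.rankdata(x), _st.rankdata(y))


# --------------------------------------------------------------------------
# hypergeometric sponge test
# --------------------------------------------------------------------------

def sponge_test(x: int, U: int, M: int, N: int, tail: str = "at_least") -> float:
    """Upper-tail hypergeometric p-value for x shared regulator miRNAs.

    p = P(X >= x) = sum_{k=x}^{min(M,N)} C(M,k) C(U-M,N-k) / C(U,N),
    exact integer arithmetic.  ``tail="above"`` gives P(X > x) instead
    (the reading under which x itself is not counted).
    """
    for name, v in (("x", x), ("U", U), ("M", M), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    x, U, M, N = int(x), int(U), int(M), int(N)
    if U < 1:
        raise ValueError("universe size U must be >= 1")
    if M > U or N > U:
        raise ValueError(f"regulator set sizes M={M}, N={N} exceed universe U={U}")
    if x > min(M, N):
        raise ValueError(f"shared count x={x} exceeds min(M, N)={min(M, N)}")
    lo = x + 1 if tail == "above" else x
    total = math.comb(U, N)
    numer = sum(math.comb(M, k) * math.comb(U - M, N - k)
                for k in range(lo, min(M, N) + 1)
                if N - k <= U - M)
    return numer / total


# --------------------------------------------------------------------------
# pipeline stages
# --------------------------------------------------------------------------

def negative_target_pairs(targets: TargetMap, mirna_expr: ExpressionMatrix,
                          target_exprs: dict[str, ExpressionMatrix],
                          de_ids: set[str] | None = None,
                          config: CernaConfig | None = None) -> pd.DataFrame:
    """Predicted miRNA–target pairs with Spearman rho strictly < scc_max.

    Spearman is rank-based, so it is computed on the TPM values
    directly.  ``de_ids``, when given, restricts retention to pairs
    whose miRNA and target are both differentially expressed.  Targets
    absent from the expression matrices are logged and skipped.
    """
    config = config or CernaConfig()
    rows, skipped = [], 0
    for mirna, tmap in sorted(targets.edges.items()):
        if mirna not in mirna_expr.data.index:
            skipped += len(tmap)
            continue
        if de_ids is not None and mirna not in de_ids:
            continue
        mv = mirna_expr.data.loc[mirna].to_numpy()
        for target, klass in sorted(tmap.items()):
            expr = target_exprs.get(klass)
            if expr is None or target not in expr.data.index:
                skipped += 1
                continue
            if de_ids is not None and target not in de_ids:
                continue
            rho = spearman_rho(mv, expr.data.loc[target].to_numpy())
            if np.isnan(rho):
                continue
            if rho < config.scc_max:
                rows.append((mirna, target, klass, rho))
    if skipped:
        log.info("negative_target_pairs: skipped %d pairs missing from expression", skipped)
    return pd.DataFrame(rows, columns=["mirna_id", "target_id", "target_class", "scc"])


@dataclass
class CernaNetwork:
    """Typed ceRNA network: an undirected graph whose nodes carry
    ``class`` and ``direction`` attributes and whose edges carry ``kind``
    (``mirna_target`` | ``cerna_pair``) and ``weight`` (rho or p), plus
    the sponge-test table backing the ceRNA edges."""

    graph: nx.Graph = field(default_factory=nx.Graph)
    sponge: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=SPONGE_COLUMNS))

    @property
    def cerna_edges(self) -> list[tuple[str, str]]:
        return [(u, v) for u, v, d in self.graph.edges(data=True) if d["kind"] == "cerna_pair"]


def build_cerna_network(co_de_by_class: dict[str, CoDESet],
                        retained_pairs: pd.DataFrame,
                        expr_by_class: dict[str, ExpressionMatrix],
                        targets: TargetMap,
                        config: CernaConfig | None = None) -> CernaNetwork:
    """Assemble the ceRNA network from retained miRNA–target pairs.

    ``co_de_by_class`` maps each RNA class to its co-DE set (cattle id
    namespace); ``expr_by_class`` supplies merged expression (all
    samples) for the partner Pearson correlations, computed on
    log2(TPM + pseudocount).
    """
    config = config or CernaConfig()
    universe = set(expr_by_class["miRNA"].data.index) if "miRNA" in expr_by_class else set()
    U = config.universe_size if config.universe_size is not None else len(universe)
    if U < 1:
        raise ValueError("miRNA universe is empty; set CernaConfig.universe_size")

    direction: dict[str, str] = {}
    for klass, codes in co_de_by_class.items():
        for i, d in codes.direction_of.items():
            direction[i] = d

    def is_de(i: str) -> bool:
        return i in direction

    # retained target ids grouped by miRNA, with classes
    class_of: dict[str, str] = {}
    by_mirna: dict[str, set[str]] = {}
    scc_of: dict[tuple[str, str], float] = {}
    for row in retained_pairs.itertuples(index=False):
        by_mirna.setdefault(row.mirna_id, set()).add(row.target_id)
        class_of[row.target_id] = row.target_class
        scc_of[(row.mirna_id, row.target_id)] = row.scc

    # regulator sets from the full predicted target map (restricted to the universe)
    regulators: dict[str, set[str]] = {}
    for mirna, tmap in targets.edges.items():
        if universe and mirna not in universe:
            continue
        for t in tmap:
            regulators.setdefault(t, set()).add(mirna)

    candidates: set[tuple[str, str]] = set()
    for shared_targets in by_mirna.values():
        for a, b in combinations(sorted(shared_targets), 2):
            if frozenset({class_of[a], class_of[b]}) in config.pair_classes:
                candidates.add((a, b))

    rows = []
    for a, b in sorted(candidates):
        if config.require_co_de and not (is_de(a) and is_de(b)):
            continue
        ea, eb = expr_by_class.get(class_of[a]), expr_by_class.get(class_of[b])
        if ea is None or eb is None or a not in ea.data.index or b not in eb.data.index:
            continue
        va = np.log2(ea.data.loc[a].to_numpy() + config.pseudocount)
        vb = np.log2(eb.data.loc[b].to_numpy() + config.pseudocount)
        pcc = pearson_r(va, vb)
        if not pcc > config.pcc_min:
            continue
        set_c = regulators.get(a, set())
        set_d = regulators.get(b, set())
        shared = sorted(set_c & set_d)
        retained_shared = [m for m in shared if a in by_mirna.get(m, set())
                           and b in by_mirna.get(m, set())]
        if not retained_shared:
            continue
        M, N = len(set_c), len(set_d)
        if M > U or N > U:
            raise ValueError(f"regulator set size exceeds universe U={U} for pair ({a}, {b})")
        p = sponge_test(len(shared), U, M, N, tail=config.tail)
        rows.append((a, b, class_of[a], class_of[b], len(shared), M, N, U, p,
                     pcc, ",".join(shared)))

    sponge = pd.DataFrame(rows, columns=SPONGE_COLUMNS)
    if len(sponge):
        from .de import benjamini_hochberg
        sponge["fdr"] = benjamini_hochberg(sponge["p"].to_numpy())
        select = sponge["fdr"] if config.bh_correct else sponge["p"]
        sponge = sponge[select < config.sponge_p_max].reset_index(drop=True)
    else:
        sponge["fdr"] = pd.Series(dtype=float)

    graph = nx.Graph()
    n_sign_consistent = 0
    for row in sponge.itertuples(index=False):
        for node in (row.gene_a, row.gene_b):
            graph.add_node(node, **{"class": class_of[node],
                                    "direction": direction.get(node, "none")})
        graph.add_edge(row.gene_a, row.gene_b, kind="cerna_pair", weight=row.p)
        for mirna in row.shared_mirnas.split(","):
            if (mirna, row.gene_a) not in scc_of and (mirna, row.gene_b) not in scc_of:
                continue
            graph.add_node(mirna, **{"class": "miRNA",
                                     "direction": direction.get(mirna, "none")})
            for partner in (row.gene_a, row.gene_b):
                if (mirna, partner) in scc_of:
                    graph.add_edge(mirna, partner, kind="mirna_target",
                                   weight=scc_of[(mirna, partner)])
                    d_m, d_t = direction.get(mirna), direction.get(partner)
                    if {d_m, d_t} == {"up", "down"}:
                        n_sign_consistent += 1
    n_target_edges = sum(1 for _u, _v, d in graph.edges(data=True)
                         if d["kind"] == "mirna_target")
    graph.graph["sign_consistent_target_edges"] = n_sign_consistent
    graph.graph["target_edges"] = n_target_edges
    if n_target_edges and n_sign_consistent < n_target_edges:
        log.info("ceRNA network: %d/%d miRNA–target edges are sign-consistent",
                 n_sign_consistent, n_target_edges)
    return CernaNetwork(graph=graph, sponge=sponge)


def extract_subnetwork(network: CernaNetwork, seed_ids, radius: int = 2) -> CernaNetwork:
    """Induced subgraph of all nodes within ``radius`` edges of any seed.

    Radius 2 reaches a seed mRNA's miRNAs and, through them, the
    competing lncRNAs/circRNAs.  Seeds absent from the network are
    ignored (empty result with a warning when none are present).
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    present = [s for s in seed_ids if s in network.graph]
    if not present:
        log.warning("extract_subnetwork: no seed present in the network")
        return CernaNetwork(graph=nx.Graph(), sponge=network.sponge.iloc[0:0])
    keep: set[str] = set()
    for seed in present:
        keep |= set(nx.single_source_shortest_path_length(network.graph, seed,
                                                          cutoff=radius))
    sub = network.graph.subgraph(keep).copy()
    pairs = {frozenset((u, v)) for u, v, d in sub.edges(data=True)
             if d["kind"] == "cerna_pair"}
    mask = np.array([frozenset((a, b)) in pairs for a, b in
                     zip(network.sponge["gene_a"], network.sponge["gene_b"])], dtype=bool)
    sponge = network.sponge.loc[mask] if len(network.sponge) else network.sponge
    return CernaNetwork(graph=sub, sponge=sponge.reset_index(drop=True))


# --------------------------------------------------------------------------
# export
# --------------------------------------------------------------------------

def write_sif(network: CernaNetwork, sif_path, node_attr_path=None) -> None:
    """Export `source<TAB>interaction<TAB>target` SIF plus node attributes."""
    with open(sif_path, "w") as fh:
        for u, v, d in sorted(network.graph.edges(data=True)):
            fh.write(f"{u}\t{d['kind']}\t{v}\n")
    if node_attr_path is not None:
        with open(node_attr_path, "w") as fh:
            fh.write("id\tclass\tdirection\n")
            for node, d in sorted(network.graph.nodes(data=True)):
                fh.write(f"{node}\t{d['class']}\t{d['direction']}\n")


def write_sponge_table(network: CernaNetwork, path) -> None:
    network.sponge.to_csv(path, sep="\t", index=False, float_format="%.17g")
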