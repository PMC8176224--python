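"""End-to-end orchestration of the analysis stages.

Stage order (mirroring the study design): simulate (or load) the
two-species bundle; per-class DE in the LAC-vs-HAC (cattle) and
LAC-vs-LWQY (yak) comparisons; projection of yak results onto cattle
ids; co-differential intersection; lncRNA association; ceRNA network
inference; enrichment; report.  ``run_all`` wires everything together
and scores the result against the planted truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cerna as _cerna
from . import de as _de
from . import enrich as _enrich
from . import lncrna as _lncrna
from . import ortholog as _ortho
from . import report as _report
from .expression import ExpressionMatrix
from .simulate import (COMPARISONS, GROUPS, ExpressionBundle, SimulationConfig,
                       TruthSet, generate_annotation, generate_expression)

log = logging.getLogger(__name__)

RNA_CLASSES = ("mRNA", "lncRNA", "miRNA", "circRNA")


def simulate(config: SimulationConfig) -> tuple[ExpressionBundle, TruthSet]:
    """Generate annotation + expression + maps + truth in one call."""
    annotation = generate_annotation(config)
    return generate_expression(config, annotation)


def run_de(bundle: ExpressionBundle, de_config: _de.DEConfig | None = None,
           lnc_config: _lncrna.LncAssocConfig | None = None
           ) -> dict[str, dict[str, pd.DataFrame]]:
    """Per-class DE tables for both comparisons.

    The lncRNA matrices are first restricted to candidate lncRNAs
    (> 200 nt, > 2 exons); yak candidates are the ortholog copies of the
    cattle candidates.
    """
    de_config = de_config or _de.DEConfig()
    candidates = _lncrna.filter_lncrna_candidates(bundle.annotation, lnc_config)
    yak_candidates = {y for c in candidates
                      for y in bundle.ortholog_map.pairs.get(c, ())}
    out: dict[str, dict[str, pd.DataFrame]] = {"LAC_vs_HAC": {}, "LAC_vs_LWQY": {}}
    for klass in RNA_CLASSES:
        cat = bundle.cattle[klass]
        yak = bundle.yak[klass]
        if klass == "lncRNA":
            cat = cat.subset(candidates)
            yak = yak.subset(yak_candidates)
        out["LAC_vs_HAC"][klass] = _de.call_de(cat, "LAC", "HAC", de_config)
        out["LAC_vs_LWQY"][klass] = _de.call_de(yak, "LAC", "LWQY", de_config)
    return out


def run_codiff(de_tables: dict[str, dict[str, pd.DataFrame]],
               omap: _ortho.OrthologMap,
               aggregation: str = "any",
               require_direction_agreement: bool = True
               ) -> dict[str, _ortho.CoDESet]:
    """Project the yak comparison to cattle ids and intersect, per class."""
    out = {}
    for klass in RNA_CLASSES:
        projected = _ortho.project_to_cattle(de_tables["LAC_vs_LWQY"][klass], omap,
                                             aggregation=aggregation)
        out[klass] = _ortho.co_differential(de_tables["LAC_vs_HAC"][klass], projected,
                                            require_direction_agreement=require_direction_agreement)
    return out


def merged_expression(bundle: ExpressionBundle,
                      groups: tuple[str, ...] = GROUPS) -> dict[str, ExpressionMatrix]:
    """Cattle-id matrices over the full sample universe.

    LAC and HAC columns come from the cattle matrices; LWQY columns are
    the per-replicate means over each cattle id's mapped yak transcripts.
    """
    out = {}
    for klass in RNA_CLASSES:
        cat = bundle.cattle[klass]
        yak = bundle.yak[klass]
        lwqy_cols = [s for s in yak.sample_ids if yak.group_of[s] == "LWQY"]
        rows = {}
        for cattle_id in cat.data.index:
            yids = [y for y in bundle.ortholog_map.pairs.get(cattle_id, ())
                    if y in yak.data.index]
            if yids:
                rows[cattle_id] = yak.data.loc[yids, lwqy_cols].mean(axis=0)
        lwqy = pd.DataFrame(rows).T.reindex(cat.data.index)
        merged = pd.concat([cat.data, lwqy], axis=1).dropna()
        mat = ExpressionMatrix(merged, species="merged", rna_class=klass)
        out[klass] = mat.subset_groups(groups) if tuple(groups) != GROUPS else mat
    return out


def run_cerna(bundle: ExpressionBundle, codesets: dict[str, _ortho.CoDESet],
              config: _cerna.CernaConfig | None = None,
              correlation_groups: tuple[str, ...] = GROUPS,
              de_ids: set[str] | None = None) -> _cerna.CernaNetwork:
    """Correlation filters + sponge test + network assembly.

    ``de_ids`` defaults to the co-DE ids of all classes (the strict
    reading); pass a wider set (e.g. DE in either comparison) together
    with ``config.require_co_de=False`` for the permissive reading.
    """
    config = config or _cerna.CernaConfig()
    merged = merged_expression(bundle, groups=correlation_groups)
    if de_ids is None:
        de_ids = {i for codes in codesets.values() for i in codes.ids}
    retained = _cerna.negative_target_pairs(bundle.targets, merged["miRNA"],
                                            merged, de_ids=de_ids, config=config)
    return _cerna.build_cerna_network(codesets, retained, merged, bundle.targets, config)


def run_lnc_associations(bundle: ExpressionBundle,
                         lnc_config: _lncrna.LncAssocConfig | None = None) -> pd.DataFrame:
    merged = merged_expression(bundle)
    return _lncrna.associate(bundle.annotation, merged["lncRNA"], merged["mRNA"],
                             lnc_config)


def run_enrichment(bundle: ExpressionBundle, codesets: dict[str, _ortho.CoDESet],
                   p_max: float = 0.05) -> pd.DataFrame:
    """Over-representation of the co-DE mRNAs against the bundle's terms,
    with all expressed mRNAs as the background."""
    background = set(bundle.cattle["mRNA"].data.index)
    study = codesets["mRNA"].ids & background
    return _enrich.fisher_enrichment(study, background, bundle.terms, p_max=p_max)


# --------------------------------------------------------------------------
# scoring against the planted truth
# --------------------------------------------------------------------------

def _precision_recall(predicted: set, truth: set) -> tuple[float, float]:
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else float("nan")
    recall = tp / len(truth) if truth else float("nan")
    return precision, recall


def score_codiff(codesets: dict[str, _ortho.CoDESet], truth: TruthSet) -> dict:
    """Precision/recall of recovered co-DE ids, overall and per class."""
    predicted = {i for codes in codesets.values() for i in codes.ids}
    planted = set(truth.co_de())
    precision, recall = _precision_recall(predicted, planted)
    per_class = {}
    for klass, codes in codesets.items():
        p, r = _precision_recall(set(codes.ids), set(truth.co_de_by_class(klass)))
        per_class[klass] = {"precision": p, "recall": r}
    return {"precision": precision, "recall": recall, "per_class": per_class}


def score_triplets(network: _cerna.CernaNetwork, truth: TruthSet) -> dict:
    """Precision/recall of predicted ceRNA pairs against planted triplets."""
    predicted = {frozenset(e) for e in network.cerna_edges}
    planted = truth.triplet_pairs()
    precision, recall = _precision_recall(predicted, planted)
    return {"precision": precision, "recall": recall,
            "n_predicted": len(predicted), "n_planted": len(planted)}


# --------------------------------------------------------------------------
# run-all
# --------------------------------------------------------------------------

@dataclass
class PipelineResult:
    bundle: ExpressionBundle
    truth: TruthSet
    de_tables: dict[str, dict[str, pd.DataFrame]]
    codesets: dict[str, _ortho.CoDESet]
    associations: pd.DataFrame
    network: _cerna.CernaNetwork
    enrichment: pd.DataFrame
    report: str
    scores: dict = field(default_factory=dict)


def run_all(sim_config: SimulationConfig,
            de_config: _de.DEConfig | None = None,
            lnc_config: _lncrna.LncAssocConfig | None = None,
            cerna_config: _cerna.CernaConfig | None = None,
            with_associations: bool = True) -> PipelineResult:
    """Simulate, run every stage in order, and score against the truth."""
    bundle, truth = simulate(sim_config)
    de_tables = run_de(bundle, de_config, lnc_config)
    codesets = run_codiff(de_tables, bundle.ortholog_map)
    network = run_cerna(bundle, codesets, cerna_config)
    associations = run_lnc_associations(bundle, lnc_config) if with_associations \
        else pd.DataFrame(columns=_lncrna.ASSOC_COLUMNS)
    enrichment = run_enrichment(bundle, codesets)
    flat_tables = {f"{comp}:{klass}": table
                   for comp, per_class in de_tables.items()
                   for klass, table in per_class.items()}
    report = _report.run_report(de_tables=flat_tables, co_de_sets=codesets,
                                network=network, enrichment=enrichment)
    scores = {"codiff": score_codiff(codesets, truth),
              "triplets": score_triplets(network, truth)}
    return PipelineResult(bundle=bundle, truth=truth, de_tables=de_tables,
                          codesets=codesets, associations=associations,
                          network=network, enrichment=enrichment,
                          report=report, scores=scores)
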