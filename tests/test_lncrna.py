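import numpy as np
import pandas as pd
import pytest

import cernapipe as cp
from cernapipe.lncrna import (GenomicAnnotation, LncAssocConfig, associate,
                              classify_antisense, classify_cis, classify_trans,
                              filter_lncrna_candidates)

from conftest import make_matrix


def annotation(rows):
    """rows: (id, start, end, strand, kind[, exon_count, length])."""
    recs = []
    for r in rows:
        rid, start, end, strand, kind = r[:5]
        exons = r[5] if len(r) > 5 else 3
        length = r[6] if len(r) > 6 else end - start + 1
        recs.append((rid, "chr1", start, end, strand, kind, exons, length))
    return GenomicAnnotation(pd.DataFrame(
        recs, columns=["id", "chrom", "start", "end", "strand", "kind",
                       "exon_count", "length"]))


class TestCandidateFilter:
    @pytest.mark.parametrize("length,exons,kept", [
        (200, 3, False),   # boundary length: strict >
        (500, 2, False),   # boundary exon count: strict >
        (500, 3, True),
        (201, 3, True),
    ])
    def test_strict_boundaries(self, length, exons, kept):
        ann = annotation([("L1", 1000, 1000 + length - 1, "+", "lncRNA", exons, length)])
        assert (("L1" in filter_lncrna_candidates(ann)) is kept)

    def test_genes_never_returned(self):
        ann = annotation([("G1", 1000, 9000, "+", "gene", 9, 8001)])
        assert filter_lncrna_candidates(ann) == set()


class TestCis:
    def test_distance_2kb(self):
        ann = annotation([("G1", 50_000, 60_000, "+", "gene"),
                          ("L1", 62_001, 63_000, "+", "lncRNA")])
        out = classify_cis(ann)
        assert len(out) == 1
        assert out.iloc[0]["evidence"] == 2_000

    @pytest.mark.parametrize("gap,is_cis", [(10_000, True), (10_001, False)])
    def test_window_boundary_inclusive(self, gap, is_cis):
        ann = annotation([("G1", 1_000, 2_000, "+", "gene"),
                          ("L1", 2_000 + gap + 1, 2_000 + gap + 500, "-", "lncRNA")])
        assert (len(classify_cis(ann)) == 1) is is_cis

    def test_overlapping_pair_is_not_cis(self):
        ann = annotation([("G1", 1_000, 2_000, "+", "gene"),
                          ("L1", 1_500, 2_500, "-", "lncRNA")])
        assert len(classify_cis(ann)) == 0

    def test_upstream_side_also_counts(self):
        ann = annotation([("G1", 50_000, 60_000, "+", "gene"),
                          ("L1", 45_000, 48_000, "+", "lncRNA")])
        out = classify_cis(ann)
        assert len(out) == 1 and out.iloc[0]["evidence"] == 1_999


class TestAntisense:
    def test_opposite_strand_overlap_51bp(self):
        ann = annotation([("G1", 100, 200, "+", "gene"),
                          ("L1", 150, 250, "-", "lncRNA")])
        anti, sense = classify_antisense(ann)
        assert len(anti) == 1 and anti.iloc[0]["evidence"] == 51
        assert len(sense) == 0

    def test_same_strand_overlap_reported_separately(self):
        ann = annotation([("G1", 100, 200, "+", "gene"),
                          ("L1", 150, 250, "+", "lncRNA")])
        anti, sense = classify_antisense(ann)
        assert len(anti) == 0 and len(sense) == 1

    def test_adjacent_non_overlapping_not_antisense(self):
        ann = annotation([("G1", 100, 200, "+", "gene"),
                          ("L1", 201, 300, "-", "lncRNA")])
        anti, _ = classify_antisense(ann)
        assert len(anti) == 0
        assert len(classify_cis(ann)) == 1  # touching => gap 0, still cis


class TestTrans:
    def test_identical_vector_is_trans(self):
        v = np.array([[1, 5, 2, 8, 3, 9.0]])
        lnc = make_matrix(v, transcript_ids=["L1"], rna_class="lncRNA")
        mrna = make_matrix(v, transcript_ids=["G1"])
        out = classify_trans(lnc, mrna)
        assert len(out) == 1
        assert out.iloc[0]["evidence"] == pytest.approx(1.0)

    def test_independent_noise_excluded(self):
        # 9 samples: chance |r| > 0.9 is vanishingly rare
        rng = np.random.default_rng(7)
        lnc = make_matrix(2 ** rng.normal(5, 1, (10, 9)), groups=("A", "B", "C"),
                          rna_class="lncRNA")
        mrna = make_matrix(2 ** rng.normal(5, 1, (10, 9)), groups=("A", "B", "C"))
        assert len(classify_trans(lnc, mrna)) == 0

    def test_sample_mismatch_raises(self):
        lnc = make_matrix(np.ones((1, 6)), rna_class="lncRNA")
        mrna = make_matrix(np.ones((1, 6)), groups=("A", "C"))
        with pytest.raises(ValueError, match="sample universe"):
            classify_trans(lnc, mrna)


class TestPrecedenceAndInvariance:
    def test_antisense_wins_over_trans(self):
        ann = annotation([("G1", 100, 200, "+", "gene"),
                          ("L1", 150, 250, "-", "lncRNA")])
        v = np.array([[1, 5, 2, 8, 3, 9.0]])
        lnc = make_matrix(v, transcript_ids=["L1"], rna_class="lncRNA")
        mrna = make_matrix(v, transcript_ids=["G1"])
        out = associate(ann, lnc, mrna)
        assert list(out["relation"]) == ["antisense"]

    def test_feature_order_shuffle_invariance(self):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(30):
            s = int(rng.integers(1, 500_000))
            kind = "gene" if i % 2 else "lncRNA"
            rows.append((f"F{i}", s, s + int(rng.integers(100, 20_000)),
                         "+" if rng.random() < 0.5 else "-", kind))
        ann = annotation(rows)
        shuffled = GenomicAnnotation(
            ann.features.sample(frac=1, random_state=1).reset_index(drop=True))
        for fn in (classify_cis, lambda a: classify_antisense(a)[0]):
            a = fn(ann).sort_values(["lncrna_id", "gene_id"]).reset_index(drop=True)
            b = fn(shuffled).sort_values(["lncrna_id", "gene_id"]).reset_index(drop=True)
            pd.testing.assert_frame_equal(a, b)

    def test_matches_bruteforce_interval_oracle(self):
        """Random annotations: all-pairs python-loop geometry agrees exactly."""
        rng = np.random.default_rng(9)
        for _ in range(200):
            rows = []
            for i in range(int(rng.integers(2, 12))):
                s = int(rng.integers(1, 60_000))
                rows.append((f"F{i}", s, s + int(rng.integers(50, 15_000)),
                             "+" if rng.random() < 0.5 else "-",
                             "gene" if rng.random() < 0.5 else "lncRNA"))
            ann = annotation(rows)
            cis_expected, anti_expected = set(), set()
            lncs = ann.of_kind("lncRNA").itertuples(index=False)
            genes = list(ann.of_kind("gene").itertuples(index=False))
            for l in lncs:
                for g in genes:
                    ov = min(l.end, g.end) - max(l.start, g.start) + 1
                    gap = max(l.start, g.start) - min(l.end, g.end) - 1
                    if ov >= 1 and l.strand != g.strand:
                        anti_expected.add((l.id, g.id, ov))
                    if ov <= 0 and 0 <= gap <= 10_000:
                        cis_expected.add((l.id, g.id, gap))
            cis_got = {(r.lncrna_id, r.gene_id, int(r.evidence))
                       for r in classify_cis(ann).itertuples(index=False)}
            anti_got = {(r.lncrna_id, r.gene_id, int(r.evidence))
                        for r in classify_antisense(ann)[0].itertuples(index=False)}
            assert cis_got == cis_expected
            assert anti_got == anti_expected
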