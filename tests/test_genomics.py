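"""Interval categorization, orientation, TADs, ceRNA detection."""

import numpy as np
import pandas as pd
import pytest

from lncreg.genomics import (CATEGORIES, candidates_for, category_table,
                             classify_pair, classify_pairs, find_cerna_pairs,
                             validate_annotation, validate_tads)


def make_annotation(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "gene_class", "chrom",
                                     "start", "end", "strand"])
    df["gene_name"] = df["gene_id"]
    for c in ("is_tf", "is_rbp", "is_enzyme"):
        df[c] = False
    return validate_annotation(df)


@pytest.fixture
def toy():
    ann = make_annotation([
        ("L1", "lncRNA", "chr1", 100, 200, "+"),
        ("G1", "mRNA", "chr1", 150, 300, "+"),
        ("G2", "mRNA", "chr1", 500_000, 510_000, "+"),
        ("G3", "mRNA", "chr1", 2_000_000, 2_010_000, "+"),
        ("G4", "mRNA", "chr2", 100, 1_000, "+"),
        ("L2", "lncRNA", "chr1", 1_200_000 + 10_000, 1_200_000 + 11_000, "+"),
    ])
    tads = validate_tads(pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr2"],
        "start": [0, 1_000_000, 0],
        "end": [1_000_000, 3_000_000, 1_000_000]}))
    return ann, tads


class TestClassifyPair:
    def test_overlap_flags_and_distance(self, toy):
        ann, tads = toy
        c = classify_pair("L1", "G1", ann, tads)
        assert c.overlapping and c.proximal and c.same_chrom and c.same_tad
        assert c.distance == -1 and c.orientation == "tandem"

    def test_proximal_and_distal(self, toy):
        ann, tads = toy
        c = classify_pair("L1", "G2", ann, tads)
        assert not c.overlapping and c.proximal and c.distance == 499_800
        c = classify_pair("L1", "G3", ann, tads)
        assert not c.proximal and c.same_chrom

    def test_trans_pair(self, toy):
        ann, tads = toy
        c = classify_pair("L1", "G4", ann, tads)
        assert not c.same_chrom and c.distance is None
        assert c.distance_str() == "X"

    def test_exact_one_megabase_gap_not_proximal(self):
        ann = make_annotation([
            ("L", "lncRNA", "chr1", 0, 1_000, "+"),
            ("A", "mRNA", "chr1", 1_001_000, 1_002_000, "+"),  # gap = 1 Mbp
            ("B", "mRNA", "chr1", 1_000_999, 1_002_000, "+"),  # gap 1 bp less
        ])
        tads = validate_tads(pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [5_000_000]}))
        assert not classify_pair("L", "A", ann, tads).proximal
        assert classify_pair("L", "B", ann, tads).proximal

    def test_same_tad_uses_five_prime_ends(self, toy):
        ann, tads = toy
        # L2 sits just inside the second chr1 TAD; G2's 5' end is in the first
        c = classify_pair("L2", "G2", ann, tads)
        assert not c.same_tad
        c = classify_pair("L2", "G3", ann, tads)
        assert c.same_tad

    def test_symmetry(self, toy):
        ann, tads = toy
        for a, b in [("L1", "G1"), ("L1", "G2"), ("L1", "G4"), ("L2", "G3")]:
            c1 = classify_pair(a, b, ann, tads)
            c2 = classify_pair(b, a, ann, tads)
            for f in ("overlapping", "same_tad", "proximal", "same_chrom",
                      "distance", "orientation"):
                assert getattr(c1, f) == getattr(c2, f)

    def test_unknown_id(self, toy):
        ann, tads = toy
        with pytest.raises(KeyError):
            classify_pair("L1", "NOPE", ann, tads)


class TestOrientation:
    """Eight strand/position cases against a hand-drawn truth table."""

    TADS = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10_000]})

    @pytest.mark.parametrize("sa,sb,left_first,expected", [
        ("+", "+", True, "tandem"),
        ("+", "+", False, "tandem"),
        ("-", "-", True, "tandem"),
        ("-", "-", False, "tandem"),
        ("+", "-", True, "convergent"),   # + upstream, 3' ends face inward
        ("+", "-", False, "divergent"),   # - upstream, 5' ends face outward
        ("-", "+", True, "divergent"),
        ("-", "+", False, "convergent"),
    ])
    def test_truth_table(self, sa, sb, left_first, expected):
        # overlapping by 50 bp; "left_first" puts gene A leftmost
        a_start, b_start = (100, 250) if left_first else (250, 100)
        ann = make_annotation([
            ("A", "lncRNA", "chr1", a_start, a_start + 200, sa),
            ("B", "mRNA", "chr1", b_start, b_start + 200, sb),
        ])
        c = classify_pair("A", "B", ann, validate_tads(self.TADS))
        assert c.overlapping
        assert c.orientation == expected

    def test_orientation_na_for_disjoint(self, toy):
        ann, tads = toy
        assert classify_pair("L1", "G2", ann, tads).orientation == "NA"


class TestTads:
    def test_overlapping_tads_rejected(self):
        bad = pd.DataFrame({"chrom": ["chr1", "chr1"],
                            "start": [0, 500], "end": [1_000, 1_500]})
        with pytest.raises(ValueError, match="overlapping TADs"):
            validate_tads(bad)

    def test_degenerate_interval_rejected(self):
        bad = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [100]})
        with pytest.raises(ValueError):
            validate_tads(bad)


class TestCerna:
    def test_shared_mirna_same_cell_line(self):
        mg = pd.DataFrame([{"mirna_id": "m1", "partner_id": "G1",
                            "partner_class": "mRNA", "cell_line": "MCF7"}])
        mlc = pd.DataFrame([{"mirna_id": "m1", "partner_id": "L1",
                             "partner_class": "lncRNA", "cell_line": "MCF7"}])
        pairs = find_cerna_pairs(mg, mlc)
        assert ("L1", "G1") in pairs
        assert pairs[("L1", "G1")] == [("m1", "MCF7")]

    def test_different_cell_lines_do_not_pair(self):
        mg = pd.DataFrame([{"mirna_id": "m1", "partner_id": "G1",
                            "partner_class": "mRNA", "cell_line": "MCF7"}])
        mlc = pd.DataFrame([{"mirna_id": "m1", "partner_id": "L1",
                             "partner_class": "lncRNA", "cell_line": "T47D"}])
        assert find_cerna_pairs(mg, mlc) == {}

    def test_planted_triplets_recovered_exactly(self):
        rng = np.random.default_rng(0)
        planted = [(f"m{i}", f"L{i}", f"G{i}", f"CL{i % 3}_{i}")
                   for i in range(30)]
        mg_rows = [{"mirna_id": m, "partner_id": g, "partner_class": "mRNA",
                    "cell_line": c} for m, _, g, c in planted]
        ml_rows = [{"mirna_id": m, "partner_id": l, "partner_class": "lncRNA",
                    "cell_line": c} for m, l, _, c in planted]
        for d in range(100):  # decoys in unique cell lines never pair
            mg_rows.append({"mirna_id": f"m{rng.integers(30)}",
                            "partner_id": f"G{rng.integers(30)}",
                            "partner_class": "mRNA",
                            "cell_line": f"DEC{d}"})
        pairs = find_cerna_pairs(pd.DataFrame(mg_rows), pd.DataFrame(ml_rows))
        assert set(pairs) == {(l, g) for _, l, g, _ in planted}


class TestCandidates:
    def test_empty_and_all(self, toy):
        ann, tads = toy
        assert candidates_for("G4", "overlapping", ann, tads) == []
        assert candidates_for("G1", "all", ann, tads) == ["L1", "L2"]

    def test_unknown_category(self, toy):
        ann, tads = toy
        with pytest.raises(ValueError, match="unknown category"):
            candidates_for("G1", "nearby", ann, tads)

    def test_category_nesting_on_synthetic_genome(self, small_bundle):
        ann = validate_annotation(small_bundle["annotation"])
        tads = validate_tads(small_bundle["tads"])
        lncs = list(ann.index[ann["gene_class"] == "lncRNA"])[:20]
        genes = list(ann.index[ann["gene_class"] == "mRNA"])[:30]
        tab = category_table(lncs, genes, ann, tads)
        assert (~tab["overlapping"] | tab["proximal"]).all()
        assert (~tab["proximal"] | tab["same_chrom"]).all()
        assert (~tab["same_tad"] | tab["same_chrom"]).all()

    def test_category_table_matches_classify_pair(self, small_bundle):
        ann = validate_annotation(small_bundle["annotation"])
        tads = validate_tads(small_bundle["tads"])
        lncs = list(ann.index[ann["gene_class"] == "lncRNA"])[:10]
        genes = list(ann.index[ann["gene_class"] == "mRNA"])[:15]
        tab = category_table(lncs, genes, ann, tads).set_index(
            ["lncrna_id", "gene_id"])
        for l in lncs:
            for g in genes:
                c = classify_pair(l, g, ann, tads)
                row = tab.loc[(l, g)]
                for f in ("overlapping", "same_tad", "proximal", "same_chrom"):
                    assert bool(row[f]) == getattr(c, f), (l, g, f)

    def test_planted_candidates_present_in_their_category(self, small_bundle):
        ann = validate_annotation(small_bundle["annotation"])
        tads = validate_tads(small_bundle["tads"])
        planted = small_bundle["planted_pairs"]
        for row in planted.itertuples(index=False):
            if row.label in ("overlapping", "same_tad", "proximal"):
                cands = candidates_for(row.gene_id, row.label, ann, tads)
                assert row.lncrna_id in cands


class TestSerializedTable:
    def test_sentinels(self, toy):
        ann, tads = toy
        tab = classify_pairs([("L1", "G1"), ("L1", "G4")], ann, tads)
        assert tab.loc[0, "dist"] == "-1" and tab.loc[0, "tandem"]
        assert tab.loc[1, "dist"] == "X"
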