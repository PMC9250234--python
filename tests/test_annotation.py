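"""Feature parsing, nearest-gene lookup, local alignment, and report
assembly."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pytest

import locogwas as lg
from locogwas.annotation import read_proteome, report_to_frame
from conftest import random_peptide

TOY_GFF = """##gff-version 3
1\tsrc\tgene\t100\t500\t.\t+\t.\tID=g1;Name=tx1
1\tsrc\tgene\t900\t1500\t.\t+\t.\tID=g2;Name=g2
1\tsrc\ttRNA\t2000\t2080\t.\t+\t.\tID=t1;Name=t1
2\tsrc\tlnc_RNA\t300\t900\t.\t-\t.\tID=l1;Name=l1
1\tsrc\tgene\tnot_a_number\t100\t.\t+\t.\tID=bad
"""


class TestParseFeatures:
    def test_toy_gff_with_malformed_line(self, tmp_path, caplog):
        path = tmp_path / "toy.gff3"
        path.write_text(TOY_GFF)
        with caplog.at_level(logging.WARNING, logger="locogwas.annotation"):
            feats = lg.parse_features(path)
        assert len(feats) == 4
        assert "malformed" in caplog.text
        classes = {f.name: f.feature_class for f in feats}
        assert classes == {"tx1": "gene", "g2": "gene", "t1": "tRNA", "l1": "lncRNA"}

    def test_point_feature_midpoint(self):
        f = lg.GeneFeature("1", 100, 100, "pt")
        assert f.midpoint == 100

    def test_name_map_rewrites_transcript(self, tmp_path):
        path = tmp_path / "toy.gff3"
        path.write_text(TOY_GFF)
        feats = lg.parse_features(path, name_map={"tx1": "prot1"})
        assert "prot1" in {f.name for f in feats}
        assert "tx1" not in {f.name for f in feats}


def _marker(name, chrom, pos):
    return lg.MarkerMeta(name, chrom, pos, ("A", "G"))


class TestNearestIndex:
    def test_hand_distances(self, toy_features):
        """Marker at 100 with midpoints {50, 90, 300}: distances 50, 10,
        200, so the two nearest are geneB (90) then geneA (50)."""
        idx = lg.build_nearest_index([_marker("m", "1", 100)], toy_features, n=2)
        names = [f.name for f, _ in idx.entries["m"]]
        dists = [d for _, d in idx.entries["m"]]
        assert names == ["geneB", "geneA"]
        assert dists == [10, 50]

    def test_marker_on_midpoint_is_first_with_zero_distance(self, toy_features):
        idx = lg.build_nearest_index([_marker("m", "1", 90)], toy_features, n=3)
        feat, dist = idx.entries["m"][0]
        assert feat.name == "geneB" and dist == 0

    def test_chromosome_without_features_gives_empty(self, toy_features):
        idx = lg.build_nearest_index([_marker("m", "9", 100)], toy_features)
        assert idx.entries["m"] == []

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(17)
        features = [
            lg.GeneFeature(str(c), int(s), int(s) + int(w), f"f{c}_{k}")
            for c in (1, 2)
            for k, (s, w) in enumerate(
                zip(rng.integers(1, 10**6, 100), rng.integers(10, 5000, 100))
            )
        ]
        markers = [
            _marker(f"m{i}", str(rng.integers(1, 3)), int(rng.integers(1, 10**6)))
            for i in range(1000)
        ]
        idx = lg.build_nearest_index(markers, features, n=10)
        for m in markers:
            cand = [f for f in features if f.chromosome == m.chromosome]
            cand.sort(key=lambda f: (abs(m.position - f.midpoint), f.midpoint))
            expected = [(f.name, m.position - f.midpoint) for f in cand[:10]]
            got = [(f.name, d) for f, d in idx.entries[m.name]]
            assert got == expected


class TestAssociateGenes:
    def test_window_zero_keeps_only_exact_midpoints(self, toy_features):
        hits = lg.associate_genes([_marker("m", "1", 90)], toy_features,
                                  mode="ld_window", param=0)
        assert [f.name for f, _ in hits["m"]] == ["geneB"]

    def test_nearest_n_beyond_feature_count(self, toy_features):
        hits = lg.associate_genes([_marker("m", "1", 100)], toy_features,
                                  mode="nearest_n", param=50)
        assert len(hits["m"]) == 3  # all chromosome-1 features, no error

    def test_window_fixture_enumeration(self, toy_features):
        # midpoints on chrom 1: 50, 90, 300; window 60 around 100 -> {50, 90}
        hits = lg.associate_genes([_marker("m", "1", 100)], toy_features,
                                  mode="ld_window", param=60)
        assert {f.name for f, _ in hits["m"]} == {"geneA", "geneB"}
        # signed distance = marker - midpoint
        assert dict((f.name, d) for f, d in hits["m"]) == {"geneA": 50, "geneB": 10}

    def test_negative_param_rejected(self, toy_features):
        with pytest.raises(ValueError):
            lg.associate_genes([], toy_features, mode="ld_window", param=-1)


def biopython_sw(a: str, b: str) -> float:
    """Independent local-alignment oracle (BLOSUM62, gap of length L costs
    11 + L, matching the implementation's affine convention)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    return float(aligner.score(a, b))


class TestSwAlign:
    def test_acde_self_score(self):
        assert lg.sw_align("ACDE", "ACDE") == 24  # BLOSUM62 diagonal 4+9+6+5

    def test_empty_sequence_scores_zero(self):
        assert lg.sw_align("ACDE", "") == 0
        assert lg.sw_align("", "ACDE") == 0

    def test_matches_biopython_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            a, b = random_peptide(rng), random_peptide(rng)
            assert lg.sw_align(a, b) == pytest.approx(biopython_sw(a, b))

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(29)
        for _ in range(10):
            a, b = random_peptide(rng), random_peptide(rng)
            assert lg.sw_align(a, b) == lg.sw_align(b, a)


class TestHomology:
    def _proteome(self, rng, n=5):
        return {
            f"sub{k}": (f"description {k}", random_peptide(rng, 40))
            for k in range(n)
        }

    def test_verbatim_query_dominates(self):
        rng = np.random.default_rng(31)
        proteome = self._proteome(rng)
        query = proteome["sub2"][1]
        assert lg.homology_best_hit(query, proteome).subject == "sub2"

    def test_evalue_decreases_with_score(self):
        from locogwas.annotation import _evalue

        assert _evalue(200, 60, 1000) < _evalue(100, 60, 1000)

    def test_best_hit_matches_exhaustive_dp_scan(self):
        rng = np.random.default_rng(37)
        proteome = self._proteome(rng)
        query = random_peptide(rng, 35)
        best = max(
            sorted(proteome),
            key=lambda name: (biopython_sw(query, proteome[name][1]), name),
        )
        # tie-break: smaller name wins in the implementation
        scores = {n: biopython_sw(query, s) for n, (_, s) in proteome.items()}
        top = max(scores.values())
        expected = min(n for n, s in scores.items() if s == top)
        hit = lg.homology_best_hit(query, proteome)
        assert hit.subject == expected
        assert hit.score == pytest.approx(top)

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError):
            lg.homology_best_hit("ACDE", {})


def _sig_report(markers):
    df = pd.DataFrame({
        "Marker": [m.name for m in markers],
        "Chrom": [m.chromosome for m in markers],
        "Pos": [m.position for m in markers],
        "P": 1e-6, "P_BH": 1e-5,
        "Significant": True, "Method": "manual",
    })
    return lg.SignificanceReport(table=df, method="manual")


class TestAssembleReport:
    def test_two_genes_two_rows(self, toy_features):
        m = _marker("m", "1", 100)
        report = _sig_report([m])
        assoc = lg.associate_genes([m], toy_features, "nearest_n", 2)
        rows = lg.assemble_report(report, assoc)
        assert len(rows) == 2
        assert {r.feature for r in rows} == {"geneA", "geneB"}

    def test_noncoding_feature_has_empty_homology(self, toy_features):
        rng = np.random.default_rng(41)
        m = _marker("m", "2", 600)
        report = _sig_report([m])
        assoc = lg.associate_genes([m], toy_features, "nearest_n", 1)
        proteomes = {"rice": {"r1": ("desc", random_peptide(rng))}}
        queries = {"lncX": random_peptide(rng)}  # even with a sequence supplied
        rows = lg.assemble_report(report, assoc, proteomes, queries)
        assert rows[0].feature_class == "lncRNA"
        assert rows[0].homology == {}
        frame = report_to_frame(rows, species=["rice"])
        assert frame.loc[0, "rice_match"] == ""

    def test_marker_without_association_yields_flagged_row(self):
        m = _marker("m", "7", 10)
        rows = lg.assemble_report(_sig_report([m]), {"m": []})
        assert len(rows) == 1 and rows[0].feature is None

    def test_pure_function_byte_identical(self, toy_features, tmp_path):
        m = _marker("m", "1", 100)
        report = _sig_report([m])
        assoc = lg.associate_genes([m], toy_features, "nearest_n", 2)
        out = []
        for k in range(2):
            frame = report_to_frame(lg.assemble_report(report, assoc))
            path = tmp_path / f"r{k}.tsv"
            frame.to_csv(path, sep="\t", index=False)
            out.append(path.read_bytes())
        assert out[0] == out[1]


def test_read_proteome_descriptions(tmp_path):
    path = tmp_path / "p.faa"
    path.write_text(">p1 some description here\nACDE\n>p2\nKLMN\n")
    db = read_proteome(path)
    assert db["p1"] == ("some description here", "ACDE")
    assert db["p2"][1] == "KLMN"
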