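"""PWM scoring, promoter scanning and network construction."""

import numpy as np
import pandas as pd
import pytest

from dmrlink.networks import (
    PWM,
    build_mirna_target_network,
    export_network,
    pwm_relative_score,
    scan_sequence,
)

REVCOMP = str.maketrans("ACGT", "TGCA")


def _random_pwm(rng, width=8):
    matrix = rng.uniform(1, 60, (4, width))
    return PWM("M1", "TFX", matrix.tolist())


def brute_force_relative_score(pwm, window, c=0.25):
    m = np.asarray(pwm.matrix) + c
    total, smin, smax = 0.0, 0.0, 0.0
    for j, base in enumerate(window):
        col = np.log2(m[:, j] / m[:, j].sum()) - np.log2(0.25)
        total += col["ACGT".index(base)]
        smin += col.min()
        smax += col.max()
    return (total - smin) / (smax - smin)


class TestRelativeScore:
    def test_consensus_scores_one_anticonsensus_zero(self):
        rng = np.random.default_rng(0)
        pwm = _random_pwm(rng)
        m = np.asarray(pwm.matrix)
        consensus = "".join("ACGT"[i] for i in m.argmax(axis=0))
        anti = "".join("ACGT"[i] for i in m.argmin(axis=0))
        assert pwm_relative_score(pwm, consensus)[0] == pytest.approx(1.0)
        assert pwm_relative_score(pwm, anti)[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_column_arithmetic(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            pwm = _random_pwm(rng)
            window = "".join(rng.choice(list("ACGT"), 8))
            ours, amb = pwm_relative_score(pwm, window)
            assert not amb
            assert ours == pytest.approx(brute_force_relative_score(pwm, window),
                                         abs=1e-12)

    def test_ambiguous_base_floors_column_and_flags(self):
        rng = np.random.default_rng(2)
        pwm = _random_pwm(rng)
        m = np.asarray(pwm.matrix)
        consensus = "".join("ACGT"[i] for i in m.argmax(axis=0))
        score, amb = pwm_relative_score(pwm, "N" + consensus[1:])
        assert amb
        assert score < 1.0

    def test_wrong_window_length_rejected(self):
        pwm = _random_pwm(np.random.default_rng(3))
        with pytest.raises(ValueError):
            pwm_relative_score(pwm, "ACGT")


class TestScanSequence:
    def test_planted_consensus_found_at_offset_with_score_one(self):
        rng = np.random.default_rng(4)
        pwm = PWM("M2", "TFY", (np.eye(4)[:, [0, 1, 2, 3, 0, 2, 1, 3]] * 97 + 1).tolist())
        seq = "".join(rng.choice(list("ACGT"), 200))
        seq = seq[:37] + pwm.consensus + seq[37 + pwm.width:]
        hits = scan_sequence(pwm, seq, threshold=0.85)
        top = max(hits, key=lambda h: h.relative_score)
        assert top.offset == 37
        assert top.relative_score == pytest.approx(1.0)

    def test_strict_inequality_excludes_perfect_hit_at_threshold_one(self):
        pwm = PWM("M3", "TFZ", (np.eye(4)[:, [0, 1, 2, 3, 0]] * 97 + 1).tolist())
        seq = "TTTT" + pwm.consensus + "TTTT"
        assert scan_sequence(pwm, seq, threshold=1.0) == []
        assert any(h.relative_score == pytest.approx(1.0)
                   for h in scan_sequence(pwm, seq, threshold=0.99))

    def test_all_offsets_match_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        pwm = _random_pwm(rng)
        seq = "".join(rng.choice(list("ACGT"), 500))
        hits = scan_sequence(pwm, seq, threshold=0.6)
        expected = []
        for strand, s in (("+", seq), ("-", seq.translate(REVCOMP)[::-1])):
            for off in range(len(s) - pwm.width + 1):
                score = brute_force_relative_score(pwm, s[off:off + pwm.width])
                if score > 0.6:
                    fwd = off if strand == "+" else len(seq) - off - pwm.width
                    expected.append((fwd, strand, round(score, 10)))
        got = [(h.offset, h.strand, round(h.relative_score, 10)) for h in hits]
        assert sorted(got) == sorted(expected)

    def test_reverse_complement_mirrors_hits(self):
        rng = np.random.default_rng(6)
        pwm = _random_pwm(rng)
        seq = "".join(rng.choice(list("ACGT"), 300))
        rc = seq.translate(REVCOMP)[::-1]
        fwd = {(h.offset, h.strand) for h in scan_sequence(pwm, seq, 0.7)}
        mirrored = {(len(seq) - h.offset - pwm.width, "+-"[h.strand == "+"])
                    for h in scan_sequence(pwm, rc, 0.7)}
        assert fwd == mirrored

    def test_short_sequence_gives_no_hits(self):
        pwm = _random_pwm(np.random.default_rng(7))
        assert scan_sequence(pwm, "ACG", 0.5) == []

    def test_raising_threshold_never_adds_hits(self):
        rng = np.random.default_rng(8)
        pwm = _random_pwm(rng)
        seq = "".join(rng.choice(list("ACGT"), 400))
        low = {(h.offset, h.strand) for h in scan_sequence(pwm, seq, 0.6)}
        high = {(h.offset, h.strand) for h in scan_sequence(pwm, seq, 0.8)}
        assert high <= low


class TestTfNetworkTruthRecovery:
    def test_planted_tf_edges_recovered_exactly(self, study):
        from dmrlink.annotate import build_promoters
        from dmrlink.integrate import identify_pmdegs
        from dmrlink.networks import build_tf_target_network
        from dmrlink.simulate import truth_dmr_frame

        ann, truth = study["annotation"], study["truth"]
        promoters = build_promoters(ann.genes, 2000, ann.chrom_sizes)
        dmr_frame = truth_dmr_frame(truth)
        pmdeg_ids = sorted(e.entity_id for e in
                           identify_pmdegs(study["deg"], dmr_frame, promoters))
        edges, nodes = build_tf_target_network(
            pmdeg_ids, promoters, ann.promoter_seqs, ann.pwms, dmr_frame,
            deg_table=study["deg"], ppi_table=ann.ppi_table)
        got = sorted((e.source, e.target, e.edge_type.removeprefix("tf_target_"))
                     for e in edges if e.edge_type.startswith("tf_target"))
        assert got == sorted(truth.planted_tf_edges)
        # no orphan edges: every endpoint is in the node table
        node_set = set(nodes["node"])
        assert all(e.source in node_set and e.target in node_set for e in edges)


class TestMirnaNetwork:
    def _scores(self):
        return pd.DataFrame({
            "mirna": ["m1"] * 4,
            "gene": ["g1", "g2", "g3", "g4"],
            "score": [51.0, 50.0, 90.0, 70.0],
        })

    def test_score_threshold_is_strict(self):
        edges, _ = build_mirna_target_network(["m1"], self._scores(),
                                              ["g1", "g2", "g3", "g4"])
        targets = {e.target for e in edges}
        assert targets == {"g1", "g3", "g4"}  # score 50 excluded

    def test_non_mdeg_candidates_excluded(self):
        edges, _ = build_mirna_target_network(["m1"], self._scores(), ["g3"])
        assert {e.target for e in edges} == {"g3"}

    def test_planted_mirna_targets_recovered_exactly(self, study):
        from dmrlink.integrate import flag_methylation_overlap
        from dmrlink.simulate import truth_dmr_frame

        ann, truth = study["annotation"], study["truth"]
        diff_all = pd.concat([study["deg"], study["demirna"]], ignore_index=True)
        linked = flag_methylation_overlap(diff_all, truth_dmr_frame(truth))
        mdegs = sorted(e.entity_id for e in linked if e.entity_kind == "gene")
        mdemirnas = sorted(e.entity_id for e in linked if e.entity_kind == "miRNA")
        assert mdemirnas == sorted(truth.planted_mirna_dmr)
        edges, _ = build_mirna_target_network(
            mdemirnas, ann.mirna_target_table, mdegs, ppi_table=ann.ppi_table)
        got = sorted(e.target for e in edges if e.edge_type == "mirna_target")
        expected = sorted(truth.planted_mirna_targets[mdemirnas[0]])
        assert got == expected


class TestExport:
    def _toy(self):
        from dmrlink.networks import RegulatoryEdge

        edges = [RegulatoryEdge("TF1", "g1", "tf_target_hyper"),
                 RegulatoryEdge("g1", "g2", "ppi")]
        nodes = pd.DataFrame({"node": ["TF1", "g1", "g2"],
                              "direction": ["not_differential", "up", "down"]})
        return edges, nodes

    def test_sif_line_count_equals_edge_count(self, tmp_path):
        edges, nodes = self._toy()
        p = tmp_path / "net.sif"
        export_network(edges, nodes, p, "sif")
        assert len(p.read_text().splitlines()) == len(edges)

    def test_graphml_roundtrip_is_byte_stable(self, tmp_path):
        import networkx as nx

        edges, nodes = self._toy()
        p1, p2 = tmp_path / "a.graphml", tmp_path / "b.graphml"
        export_network(edges, nodes, p1, "graphml")
        g = nx.read_graphml(p1)
        nx.write_graphml(g, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_network_and_unknown_format(self, tmp_path):
        export_network([], pd.DataFrame(columns=["node", "direction"]),
                       tmp_path / "e.tsv", "tsv")
        assert (tmp_path / "e.tsv").read_text().startswith("source")
        with pytest.raises(ValueError):
            export_network([], pd.DataFrame(columns=["node", "direction"]),
                           tmp_path / "x.bin", "bin")
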