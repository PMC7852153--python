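"""Seed matching, shared-miRNA network construction, and export round trips."""

from itertools import product

import numpy as np
import pytest

from lncsuite.cerna import (
    MiRNABindingSite,
    build_cerna_network,
    export_network,
    find_seed_matches,
    import_network,
    scan_targets,
    write_site_table,
    _revcomp,
    _norm,
)

MIRNA = "UGAGGUAGUAGGUUGUAUAGUU"  # a canonical 22-mer


def seed7(mirna):
    return _norm(mirna)[1:8]


class TestSeedMatches:
    def test_constructed_7mer_m8_site(self):
        site = _revcomp(seed7(MIRNA))
        target = "C" * 40 + site + "C" * 40
        hits = find_seed_matches(MIRNA, target)
        assert len(hits) == 1
        assert hits[0].position == 40 and hits[0].site_type == "7mer-m8"

    def test_8mer_site_takes_precedence(self):
        site = _revcomp(seed7(MIRNA)) + "A"
        target = "C" * 30 + site + "C" * 30
        hits = find_seed_matches(MIRNA, target)
        assert [h.site_type for h in hits] == ["8mer"]

    def test_7mer_a1_site(self):
        site = _revcomp(_norm(MIRNA)[1:7]) + "A"
        # pad with G so the base before the core cannot complete the full
        # 7mer-m8 core (which would upgrade the site to an 8mer)
        target = "G" * 30 + site + "G" * 30
        hits = find_seed_matches(MIRNA, target)
        assert [h.site_type for h in hits] == ["7mer-A1"]
        assert hits[0].position == 30

    def test_no_complementary_site_empty(self):
        assert find_seed_matches(MIRNA, "A" * 100) == []

    def test_tandem_8mer_sites_positions_differ_by_repeat(self):
        unit = _revcomp(seed7(MIRNA)) + "A" + "CCGG"
        target = "C" * 10 + unit + unit + "C" * 10
        hits = find_seed_matches(MIRNA, target)
        eights = [h for h in hits if h.site_type == "8mer"]
        assert len(eights) == 2
        assert eights[1].position - eights[0].position == len(unit)

    def test_u_t_equivalence(self):
        site = _revcomp(seed7(MIRNA))
        rna_target = ("C" * 20 + site + "C" * 20).replace("T", "U")
        assert len(find_seed_matches(MIRNA, rna_target)) == 1

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError):
            find_seed_matches("ACGUACG", "ACGT" * 30)

    def test_sites_self_verify_against_seed(self, dataset):
        """Every reported site region, reverse-complemented, equals the
        corresponding miRNA seed region."""
        targets = dict(list(dataset.sequences.items())[:40])
        for s in scan_targets(dataset.mirnas, targets):
            region = _norm(dataset.sequences[s.target_id])[s.position : s.position + s.length]
            m = _norm(dataset.mirnas[s.mirna_id])
            if s.site_type == "8mer":
                assert region == _revcomp(m[1:8]) + "A"
            elif s.site_type == "7mer-m8":
                assert region == _revcomp(m[1:8])
            else:
                assert region == _revcomp(m[1:7]) + "A"

    def test_planted_sites_recovered(self, dataset):
        for _, row in dataset.site_truth.iterrows():
            hits = find_seed_matches(
                dataset.mirnas[row["mirna_id"]],
                dataset.sequences[row["target_id"]],
                row["mirna_id"],
                row["target_id"],
            )
            assert any(
                h.position == row["position"] and h.site_type == row["site_type"]
                for h in hits
            )


def site(mid, tid):
    return MiRNABindingSite(mid, tid, 0, "7mer-m8", 7)


def brute_force_edges(lnc_sites, mrna_sites):
    lmap, gmap = {}, {}
    for s in lnc_sites:
        lmap.setdefault(s.target_id, set()).add(s.mirna_id)
    for s in mrna_sites:
        gmap.setdefault(s.target_id, set()).add(s.mirna_id)
    return {
        (l, g, frozenset(lmap[l] & gmap[g]))
        for l, g in product(lmap, gmap)
        if lmap[l] & gmap[g]
    }


class TestNetwork:
    def test_single_shared_mirna_edge(self):
        net = build_cerna_network(
            [site("m1", "L1"), site("m2", "L1")],
            [site("m1", "G1"), site("m3", "G2")],
        )
        assert net.cerna_edges() == [("L1", "G1", frozenset({"m1"}))]

    def test_no_shared_mirnas_no_edges(self):
        net = build_cerna_network([site("m1", "L1")], [site("m2", "G1")])
        assert net.cerna_edges() == []

    def test_multiple_shared_mirnas_single_edge(self):
        net = build_cerna_network(
            [site("m1", "L1"), site("m2", "L1")],
            [site("m1", "G1"), site("m2", "G1")],
        )
        edges = net.cerna_edges()
        assert len(edges) == 1 and edges[0][2] == frozenset({"m1", "m2"})

    def test_id_collision_rejected(self):
        with pytest.raises(ValueError):
            build_cerna_network([site("m1", "X")], [site("m1", "X")])

    def test_equals_brute_force_on_random_instances(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            n_m = int(rng.integers(1, 8))
            n_l = int(rng.integers(1, 20))
            n_g = int(rng.integers(1, 25))
            lnc_sites = [
                site(f"m{rng.integers(n_m)}", f"L{rng.integers(n_l)}")
                for _ in range(int(rng.integers(0, 40)))
            ]
            mrna_sites = [
                site(f"m{rng.integers(n_m)}", f"G{rng.integers(n_g)}")
                for _ in range(int(rng.integers(0, 40)))
            ]
            net = build_cerna_network(lnc_sites, mrna_sites)
            got = {(u, v, s) for u, v, s in net.cerna_edges()}
            got = {(u, v, s) if u.startswith("L") else (v, u, s) for u, v, s in got}
            assert got == brute_force_edges(lnc_sites, mrna_sites)

    def test_adding_binding_edge_is_monotone(self):
        rng = np.random.default_rng(22)
        lnc_sites = [site(f"m{i%3}", f"L{i%4}") for i in range(8)]
        mrna_sites = [site(f"m{(i+1)%3}", f"G{i%5}") for i in range(8)]
        base = build_cerna_network(lnc_sites, mrna_sites)
        base_edges = {(u, v) for u, v, _ in base.cerna_edges()}
        more = build_cerna_network(lnc_sites + [site("m0", "L0")], mrna_sites)
        more_edges = {(u, v) for u, v, _ in more.cerna_edges()}
        assert base_edges <= more_edges

    def test_focal_subnetwork_restricts_to_one_lncrna(self):
        net = build_cerna_network(
            [site("m1", "L1"), site("m2", "L2")],
            [site("m1", "G1"), site("m2", "G2")],
        )
        focal = net.focal_subnetwork("L1")
        assert focal.lncrnas == {"L1"}
        assert {e[:2] for e in focal.cerna_edges()} == {("L1", "G1")}

    def test_planted_wiring_yields_expected_edges(self, dataset):
        truth = dataset.truth
        lnc_ids = set(truth.index[truth["is_novel_lnc"]])
        lnc_seqs = {i: dataset.sequences[i] for i in lnc_ids}
        mrna_seqs = {
            t.id: dataset.sequences[t.id]
            for t in dataset.annotation
            if t.biotype == "known_mRNA"
        }
        net = build_cerna_network(
            scan_targets(dataset.mirnas, lnc_seqs),
            scan_targets(dataset.mirnas, mrna_seqs),
        )
        planted_l, planted_g = {}, {}
        for _, row in dataset.site_truth.iterrows():
            d = planted_l if row["target_id"] in lnc_ids else planted_g
            d.setdefault(row["target_id"], set()).add(row["mirna_id"])
        expected = {
            (l, g)
            for l in planted_l
            for g in planted_g
            if planted_l[l] & planted_g[g]
        }
        got = {
            (u, v) if u in lnc_ids else (v, u) for u, v, _ in net.cerna_edges()
        }
        assert expected <= got


class TestExport:
    def build(self):
        return build_cerna_network(
            [site("m1", "L1")], [site("m1", "G1")]
        )

    def test_sif_rows(self, tmp_path):
        path = tmp_path / "n.sif"
        export_network(self.build(), path, "SIF")
        rows = path.read_text().strip().split("\n")
        assert len(rows) == 3
        assert sum("\tbinds\t" in r for r in rows) == 2
        assert sum("\tceRNA\t" in r for r in rows) == 1

    def test_empty_network_valid_file(self, tmp_path):
        net = build_cerna_network([], [])
        path = tmp_path / "e.sif"
        export_network(net, path, "SIF")
        assert path.read_text() == ""

    @pytest.mark.parametrize("fmt", ["SIF", "GraphML"])
    def test_round_trip_preserves_edge_sets(self, tmp_path, fmt):
        net = build_cerna_network(
            [site("m1", "L1"), site("m2", "L1"), site("m2", "L2")],
            [site("m1", "G1"), site("m2", "G1"), site("m3", "G2")],
        )
        p1 = tmp_path / f"a.{fmt.lower()}"
        p2 = tmp_path / f"b.{fmt.lower()}"
        export_network(net, p1, fmt)
        back = import_network(p1, fmt)
        export_network(back, p2, fmt)
        if fmt == "SIF":
            assert p1.read_text() == p2.read_text()
        else:
            again = import_network(p2, fmt)
            assert set(map(tuple, back.binding_edges())) == set(
                map(tuple, again.binding_edges())
            )
            assert set(back.cerna_edges()) == set(again.cerna_edges())

    def test_site_table(self, tmp_path):
        path = tmp_path / "sites.tsv"
        write_site_table([site("m1", "L1")], path)
        assert "m1\tL1\t0\t7mer-m8" in path.read_text()
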