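"""Signature derivation, shared-DEG intersections, direction profiling."""

import numpy as np
import pytest

from eomsc import signatures as sig
from tests.conftest import make_deg_table, random_deg_tables


class TestMediumSignatures:
    def test_gene_up_in_one_genotype_only_is_excluded(self):
        wt = make_deg_table("G", "D", [("a", 1.0, 1e-9, 1e-9), ("b", 1.0, 1e-9, 1e-9)])
        mut = make_deg_table("G", "D", [("a", 1.0, 1e-9, 1e-9), ("b", 0.1, 0.5, 0.9)])
        out = sig.derive_activation_signature(wt, mut)
        assert out.genes == ["a"]

    def test_empty_tables_give_empty_signature(self):
        wt = make_deg_table("G", "D", [])
        mut = make_deg_table("G", "D", [])
        assert len(sig.derive_activation_signature(wt, mut)) == 0

    def test_matches_brute_force_sign_filtered_intersection(self):
        rng = np.random.default_rng(0)
        rows_wt = [(f"g{i}", rng.normal(), 1e-9, rng.choice([1e-9, 0.5])) for i in range(20)]
        rows_mut = [(f"g{i}", rng.normal(), 1e-9, rng.choice([1e-9, 0.5])) for i in range(20)]
        wt = make_deg_table("G", "D", rows_wt)
        mut = make_deg_table("G", "D", rows_mut)
        got = set(g.lower() for g in sig.derive_activation_signature(wt, mut).genes)
        brute = {
            g.lower()
            for (g, l1, _, a1), (_, l2, __, a2) in zip(rows_wt, rows_mut)
            if l1 >= 0.4 and a1 <= 0.001 and l2 >= 0.4 and a2 <= 0.001
        }
        assert got == brute

    def test_activation_and_differentiation_are_disjoint(self):
        rng = np.random.default_rng(1)
        rows = [(f"g{i}", rng.normal(), 1e-9, 1e-9) for i in range(30)]
        wt = make_deg_table("G", "D", rows)
        act = sig.derive_activation_signature(wt, wt)
        diff = sig.derive_differentiation_signature(wt, wt)
        assert act.keys().isdisjoint(diff.keys())

    def test_zero_lfc_gene_in_neither(self):
        wt = make_deg_table("G", "D", [("flat", 0.0, 1e-9, 1e-9)])
        assert len(sig.derive_activation_signature(wt, wt)) == 0
        assert len(sig.derive_differentiation_signature(wt, wt)) == 0

    def test_mismatched_contrasts_rejected(self):
        a = make_deg_table("G", "D", [])
        b = make_deg_table("D", "G", [])
        with pytest.raises(ValueError, match="mismatched"):
            sig.derive_activation_signature(a, b)


class TestQuiescenceSignature:
    def test_builtin_extension_is_exactly_18_markers(self):
        s = sig.load_quiescence_signature()
        assert len(s) == 18
        assert "Notch1" in s and "Cav1" in s

    def test_union_with_curated_file_deduplicates(self, tmp_path):
        f = tmp_path / "quiescence.txt"
        f.write_text("Notch1\nNewGene1\nNewGene2\n")
        s = sig.load_quiescence_signature(f)
        assert len(s) == 18 + 2  # Notch1 collapses

    def test_case_variants_collapse(self, tmp_path):
        f = tmp_path / "q.txt"
        f.write_text("VCAM1\nvcam1\n")
        s = sig.load_quiescence_signature(f)
        assert len(s) == 18


class TestSharedDegs:
    def test_gene_missing_from_one_table_is_excluded(self):
        rows = [("a", 1.0, 1e-9, 1e-9), ("b", 1.0, 1e-9, 1e-9)]
        t1 = make_deg_table("EOM", "HL", rows)
        t2 = make_deg_table("EOM", "Dia", rows[:1])
        s = sig.shared_degs([t1, t2], "EOM")
        assert s.genes == ["a"]

    def test_direction_consistency_flags(self):
        t1 = make_deg_table("EOM", "HL", [("u", 1.0, 1e-9, 1e-9), ("d", -1, 1e-9, 1e-9), ("m", 1, 1e-9, 1e-9)])
        t2 = make_deg_table("EOM", "Dia", [("u", 0.5, 1e-9, 1e-9), ("d", -2, 1e-9, 1e-9), ("m", -1, 1e-9, 1e-9)])
        s = sig.shared_degs([t1, t2], "EOM")
        assert s.up == ["u"] and s.down == ["d"]
        assert "m" in s.genes

    def test_matches_brute_force_nested_loop(self):
        rng = np.random.default_rng(2)
        for trial in range(100):
            tables = random_deg_tables(rng, n_tables=rng.integers(2, 5), n_genes=15)
            s = sig.shared_degs(tables, "EOM", lfc_min=0.4, adj_max=0.01)
            # brute force
            per = []
            for t in tables:
                d = {}
                for _, r in t.table.iterrows():
                    if abs(r["log2fc"]) >= 0.4 and r["adj"] <= 0.01:
                        d[r["gene"].lower()] = r["log2fc"]
                per.append(d)
            inter = set(per[0])
            for d in per[1:]:
                inter &= set(d)
            assert {g.lower() for g in s.genes} == inter
            assert {g.lower() for g in s.up} == {g for g in inter if all(d[g] > 0 for d in per)}
            assert {g.lower() for g in s.down} == {g for g in inter if all(d[g] < 0 for d in per)}

    def test_table_order_does_not_matter(self):
        rng = np.random.default_rng(3)
        tables = random_deg_tables(rng, n_tables=3, n_genes=25)
        a = sig.shared_degs(tables, "EOM")
        b = sig.shared_degs(tables[::-1], "EOM")
        assert a.genes == b.genes and a.up == b.up and a.down == b.down

    def test_fewer_than_two_tables_rejected(self):
        with pytest.raises(ValueError):
            sig.shared_degs([make_deg_table("EOM", "HL", [])], "EOM")

    def test_size_bounded_by_smallest_table(self):
        rng = np.random.default_rng(4)
        tables = random_deg_tables(rng, n_tables=3, n_genes=30)
        s = sig.shared_degs(tables, "EOM", lfc_min=0.0, adj_max=1.0)
        assert len(s.genes) <= min(len(t.table) for t in tables)


class TestProfileAndEom:
    def test_disjoint_signature_gives_empty_profile(self):
        t1 = make_deg_table("EOM", "HL", [("a", 1, 1e-9, 1e-9)])
        t2 = make_deg_table("EOM", "Dia", [("a", 1, 1e-9, 1e-9)])
        s = sig.shared_degs([t1, t2], "EOM")
        prof = sig.signature_direction_profile(s, [sig.SignatureSet("quiescence", ["zzz"])])
        assert prof.empty

    def test_partition_bound_and_subgroup_tags(self):
        rows = [("Notch1", 1, 1e-9, 1e-9), ("Pax7", -1, 1e-9, 1e-9), ("Klf4", 1, 1e-9, 1e-9)]
        t1 = make_deg_table("EOM", "HL", rows)
        t2 = make_deg_table("EOM", "Dia", rows)
        s = sig.shared_degs([t1, t2], "EOM")
        q = sig.SignatureSet("quiescence", ["Notch1", "Pax7", "Klf4", "Other"])
        prof = sig.signature_direction_profile(s, [q])
        assert len(prof) == 3
        tags = dict(zip(prof["gene"], prof["subgroup"]))
        assert tags == {"Notch1": "notch", "Pax7": "sc_marker", "Klf4": "pluripotency"}
        n_up = (prof["direction"] == "up").sum()
        n_down = (prof["direction"] == "down").sum()
        assert n_up + n_down <= len(prof)

    def test_eom_signature_is_plain_intersection(self):
        assert sig.eom_signature(["a", "b", "c"], ["b", "c", "d"]).genes == ["b", "c"]
        assert sig.eom_signature(["a"], ["b"]).genes == []
        e = sig.eom_signature(["x", "y"], ["X"])
        assert [g.lower() for g in e.genes] == ["x"]


class TestExport:
    def test_round_trip(self, tmp_path):
        s = sig.SignatureSet("eom", ["b", "A", "c"])
        (path,) = sig.export_gene_lists([s], tmp_path)
        back = sig.read_gene_list(path)
        assert {g.lower() for g in back} == s.keys()
        # deterministic sorted order on disk
        assert path.read_text().splitlines() == sorted(s.genes)

    def test_empty_set_creates_empty_file(self, tmp_path):
        (path,) = sig.export_gene_lists([sig.SignatureSet("empty", [])], tmp_path)
        assert path.exists() and path.read_text() == ""
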