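import itertools
import math
from collections import Counter

import numpy as np
import pytest

import sitelink as sl

from conftest import column_alignment


def brute_force_nmi(x, y):
    """Independent plug-in NMI oracle over the explicit joint table."""
    pairs = [(a, b) for a, b in zip(x, y) if a != "-" and b != "-"]
    n = len(pairs)

    def H(counter):
        return -sum((c / n) * math.log(c / n) for c in counter.values())

    hx = H(Counter(a for a, _ in pairs))
    hy = H(Counter(b for _, b in pairs))
    hxy = H(Counter(pairs))
    if hx == 0 or hy == 0:
        return 0.0
    return (hx + hy - hxy) / min(hx, hy)


class TestPairwiseNMI:
    def test_identical_columns_score_one(self):
        x = "AV" * 20 + "LILI"
        aln = column_alignment(x, x)
        m = sl.pairwise_nmi(aln, [1, 2])
        assert m.value(1, 2) == pytest.approx(1.0, abs=1e-12)

    def test_bijective_recoding_scores_one(self):
        x = "AAVVAVAV" * 5
        y = x.replace("A", "w").replace("V", "A").replace("w", "V")
        aln = column_alignment(x, y)
        assert sl.nmi_pair(list(x), list(y)) == pytest.approx(1.0, abs=1e-12)

    def test_exact_product_composition_scores_zero(self):
        # joint counts exactly n_x(a) * n_y(b): plug-in MI vanishes
        x, y = [], []
        for a, na in (("A", 50), ("V", 55)):
            for b, nb in (("L", 50), ("I", 55)):
                x.extend([a] * (na * nb))
                y.extend([b] * (na * nb))
        assert sl.nmi_pair(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_partial_coupling_matches_brute_force_oracle(self):
        x = ["A"] * 60 + ["V"] * 45
        y = ["V"] * 5 + ["A"] * 55 + ["V"] * 45  # x with 5 rows flipped
        expected = brute_force_nmi(x, y)
        assert expected == pytest.approx(0.7733202830143792, abs=1e-12)
        assert sl.nmi_pair(x, y) == pytest.approx(expected, abs=1e-12)

    def test_symmetry_range_and_relabeling_on_random_pairs(self):
        rng = np.random.default_rng(11)
        relabel = dict(zip("ACDV", "WYFM"))
        for _ in range(200):
            x = rng.choice(list("ACDV"), size=50)
            y = rng.choice(list("ACDV"), size=50)
            v = sl.nmi_pair(x, y)
            assert 0.0 <= v <= 1.0
            assert sl.nmi_pair(y, x) == pytest.approx(v, abs=1e-12)
            y2 = [relabel[c] for c in y]
            assert sl.nmi_pair(x, y2) == pytest.approx(v, abs=1e-12)
            assert v == pytest.approx(brute_force_nmi(list(x), list(y)), abs=1e-10)

    def test_zero_entropy_column_scores_zero(self):
        aln = column_alignment("A" * 20, "AV" * 10)
        assert sl.pairwise_nmi(aln, [1, 2]).value(1, 2) == 0.0

    def test_sparse_joint_coverage_guard(self):
        # only 4/20 jointly non-gap rows: below the default 50% floor -> 0
        x = "AVAV" + "-" * 16
        y = "AVAV" + "LI" * 8
        assert sl.nmi_pair(list(x), list(y)) == 0.0

    def test_gapped_rows_dropped_from_joint_table(self):
        x = list("AAVV") + ["-"] * 2
        y = list("LLII") + ["L", "I"]
        v = sl.nmi_pair(x, y, min_joint_fraction=0.1)
        assert v == pytest.approx(brute_force_nmi(x, y), abs=1e-12)

    def test_fewer_than_two_columns_is_an_error(self):
        aln = column_alignment("AVAV")
        with pytest.raises(ValueError):
            sl.pairwise_nmi(aln, [1])


class TestSRMode:
    def _identical_columns(self, k, pattern="ACDEFGHI"):
        col = (pattern * 14)[:105]
        return column_alignment(*([col] * k))

    @pytest.mark.parametrize("order, maximum", [
        (2, 1.0), (3, 2 / 3), (4, 0.5), (5, 0.4), (10, 0.2),
    ])
    def test_maximum_on_fully_redundant_clusters(self, order, maximum):
        aln = self._identical_columns(order)
        value = sl.srmode(aln, list(range(1, order + 1)))
        assert value == pytest.approx(maximum, abs=1e-12)

    def test_duplicate_members_rejected(self):
        aln = self._identical_columns(3)
        with pytest.raises(ValueError):
            sl.srmode(aln, [1, 2, 2])

    @pytest.mark.parametrize("members", [[1], list(range(1, 12))])
    def test_order_bounds(self, members):
        aln = self._identical_columns(11)
        with pytest.raises(ValueError):
            sl.srmode(aln, members)

    def test_bound_two_over_n_on_random_clusters(self):
        rng = np.random.default_rng(5)
        grid = rng.choice(list("ACDV"), size=(40, 30))
        aln = sl.Alignment(
            row_ids=[f"s{i}" for i in range(40)], residues=grid,
            column_positions=list(range(1, 31)),
        )
        nmi = sl.pairwise_nmi(aln, list(range(1, 31)))
        for _ in range(500):
            n = int(rng.integers(2, 11))
            members = sorted(rng.choice(np.arange(1, 31), size=n, replace=False))
            value = sl.srmode(aln, [int(p) for p in members], nmi=nmi)
            assert value <= 2.0 / n + 1e-9
            if value >= 2.0 / n - 1e-9:
                for a, b in itertools.combinations(members, 2):
                    assert nmi.value(int(a), int(b)) == pytest.approx(1.0, abs=1e-9)

    def test_independent_columns_score_near_zero(self):
        # Monte-Carlo null: 5 independent uniform 4-letter columns, 105 rows
        rng = np.random.default_rng(17)
        below = 0
        replicates = 1000
        for _ in range(replicates):
            cols = ["".join(rng.choice(list("ACDV"), size=105)) for _ in range(5)]
            aln = column_alignment(*cols)
            if sl.srmode(aln, [1, 2, 3, 4, 5]) < 0.05:
                below += 1
        assert below / replicates >= 0.95


class TestBuildClusters:
    def test_planted_triple_is_top_third_order_cluster(self):
        spec = sl.SyntheticSpec(
            n_species=105, n_columns=50,
            planted_groups=[sl.PlantedGroup(columns=(10, 25, 40), noise=0.0)],
            seed=123,
        )
        aln, _ = sl.generate_msa(spec)
        report = sl.build_clusters(aln, list(range(1, 51)), max_order=3)
        assert report.top(3).members == [10, 25, 40]
        assert report.top(3).srmode == pytest.approx(2 / 3, abs=1e-12)

    def test_two_disjoint_planted_pairs_recovered(self):
        spec = sl.SyntheticSpec(
            n_species=105, n_columns=40,
            planted_groups=[
                sl.PlantedGroup(columns=(5, 15), noise=0.0),
                sl.PlantedGroup(columns=(22, 33), noise=0.0),
            ],
            seed=321,
        )
        aln, _ = sl.generate_msa(spec)
        report = sl.build_clusters(aln, list(range(1, 41)), max_order=3)
        top_two = {tuple(c.members) for c in report.clusters_by_order[2][:2]}
        assert top_two == {(5, 15), (22, 33)}
        # neither pair's order-3 extension outranks them: extensions add an
        # independent column, so their SRMode drops well below the pair scores
        order3 = report.clusters_by_order[3]
        extended = [c for c in order3 if c.parent in top_two]
        assert all(c.srmode < 0.5 for c in extended)

    def test_nested_hierarchy(self):
        rng = np.random.default_rng(9)
        grid = rng.choice(list("ACDVLI"), size=(30, 15))
        aln = sl.Alignment(
            row_ids=[f"s{i}" for i in range(30)], residues=grid,
            column_positions=list(range(1, 16)),
        )
        report = sl.build_clusters(aln, list(range(1, 16)), max_order=6)
        for order in range(3, 7):
            parents = {c.key() for c in report.clusters_by_order[order - 1]}
            for cl in report.clusters_by_order[order]:
                assert cl.parent in parents
                assert set(cl.parent) < set(cl.members)

    def test_deterministic_report(self):
        rng = np.random.default_rng(2)
        grid = rng.choice(list("ACDV"), size=(25, 12))
        aln = sl.Alignment(
            row_ids=[f"s{i}" for i in range(25)], residues=grid,
            column_positions=list(range(1, 13)),
        )
        r1 = sl.build_clusters(aln, list(range(1, 13)), max_order=5)
        r2 = sl.build_clusters(aln, list(range(1, 13)), max_order=5)
        assert r1.index_frame().equals(r2.index_frame())

    def test_clusters_sorted_by_descending_srmode(self):
        spec = sl.SyntheticSpec(
            n_species=60, n_columns=20,
            planted_groups=[sl.PlantedGroup(columns=(2, 8), noise=0.1)],
            seed=77,
        )
        aln, _ = sl.generate_msa(spec)
        report = sl.build_clusters(aln, list(range(1, 21)), max_order=4)
        for clusters in report.clusters_by_order.values():
            scores = [c.srmode for c in clusters]
            assert scores == sorted(scores, reverse=True)

    def test_retained_fewer_than_two_is_an_error(self):
        aln = column_alignment("AVAV", "AVAV")
        with pytest.raises(ValueError):
            sl.build_clusters(aln, [1])

    @pytest.mark.parametrize("max_order", [1, 11])
    def test_max_order_bounds(self, max_order):
        aln = column_alignment("AVAV", "VAVA")
        with pytest.raises(ValueError):
            sl.build_clusters(aln, [1, 2], max_order=max_order)

    def test_no_overlap_mode_uses_each_column_once_per_order(self):
        rng = np.random.default_rng(4)
        grid = rng.choice(list("ACDV"), size=(30, 14))
        aln = sl.Alignment(
            row_ids=[f"s{i}" for i in range(30)], residues=grid,
            column_positions=list(range(1, 15)),
        )
        report = sl.build_clusters(
            aln, list(range(1, 15)), max_order=4, allow_overlap=False
        )
        for order in (3, 4):
            used = list(
                itertools.chain.from_iterable(
                    c.members for c in report.clusters_by_order[order]
                )
            )
            assert len(used) == len(set(used))

    def test_column_data_layout(self):
        spec = sl.SyntheticSpec(
            n_species=10, n_columns=6,
            planted_groups=[sl.PlantedGroup(columns=(1, 4), noise=0.0)],
            seed=8,
        )
        aln, _ = sl.generate_msa(spec)
        report = sl.build_clusters(aln, list(range(1, 7)), max_order=2)
        top = report.top(2)
        block = report.column_data(aln, top)
        assert block.shape == (10, 2)
        assert list(block.index) == aln.row_ids

    def test_report_writers(self, tmp_path):
        spec = sl.SyntheticSpec(
            n_species=12, n_columns=8,
            planted_groups=[sl.PlantedGroup(columns=(2, 5, 7), noise=0.0)],
            seed=15,
        )
        aln, _ = sl.generate_msa(spec)
        report = sl.build_clusters(aln, list(range(1, 9)), max_order=3)
        paths = sl.write_cluster_csv(report, aln, tmp_path / "clusters")
        assert (tmp_path / "clusters" / "clusters_index.csv").exists()
        assert len(paths) == 3  # index + order2 + order3
        xlsx = sl.write_cluster_xlsx(report, aln, tmp_path / "clusters.xlsx")
        import openpyxl

        wb = openpyxl.load_workbook(xlsx)
        assert set(wb.sheetnames) == {"index", "order2", "order3"}
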