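import numpy as np
import pytest

from leafnet import coloc, synthetic as syn
from leafnet.types import GeneModel, Peak, PeakSet

PARTNERS = [f"T{i:02d}" for i in range(12)]
PLANTED = PARTNERS[:4]


def make_peak(chrom, summit, signal, tf):
    return Peak(chrom=chrom, start=summit - 100, end=summit + 100,
                summit=summit, signal=signal, tf=tf)


class TestNormalizedRanks:
    def test_endpoints(self):
        ps = PeakSet("A", [make_peak("c1", 1000 * i, float(i), "A")
                           for i in range(1, 6)])
        ranks = dict(zip([p.signal for p in ps.peaks], coloc.normalized_ranks(ps)))
        assert ranks[5.0] == 1.0
        assert ranks[1.0] == 0.0

    def test_middle_value(self):
        ps = PeakSet("A", [make_peak("c1", 1000 * i, float(i), "A")
                           for i in range(1, 6)])
        ranks = dict(zip([p.signal for p in ps.peaks], coloc.normalized_ranks(ps)))
        assert ranks[3.0] == 0.5

    def test_tied_top_average_rank(self):
        ps = PeakSet("A", [
            make_peak("c1", 1000, 9.0, "A"),
            make_peak("c1", 2000, 9.0, "A"),
            make_peak("c1", 3000, 1.0, "A"),
        ])
        ranks = coloc.normalized_ranks(ps)
        assert ranks[0] == ranks[1] == pytest.approx(0.75)

    def test_single_peak(self):
        ps = PeakSet("A", [make_peak("c1", 1000, 3.0, "A")])
        assert coloc.normalized_ranks(ps).tolist() == [1.0]

    def test_empty_error(self):
        with pytest.raises(ValueError):
            coloc.normalized_ranks(PeakSet("A", []))


GENES = [GeneModel("g1", "c1", 500_000, 502_000, "+")]


class TestBuildColocMatrix:
    def setup_method(self):
        self.focus = PeakSet("F", [
            make_peak("c1", 10_000, 5.0, "F"),
            make_peak("c1", 20_000, 3.0, "F"),
            make_peak("c1", 501_000, 4.0, "F"),  # genic row
        ])

    def test_non_overlapping_partner_all_zero(self):
        partner = PeakSet("P", [make_peak("c1", 900_000, 2.0, "P")])
        M = coloc.build_coloc_matrix(self.focus, [partner], GENES)
        assert np.all(M.matrix[:, 0] == 0)

    def test_identical_partner_matches_own_ranks(self):
        twin = PeakSet("P", [
            make_peak(p.chrom, p.summit, p.signal, "P") for p in self.focus.peaks
        ])
        M = coloc.build_coloc_matrix(self.focus, [twin], GENES)
        np.testing.assert_allclose(
            M.matrix[:, 0], coloc.normalized_ranks(self.focus)
        )

    def test_two_summits_in_one_peak_takes_max(self):
        partner = PeakSet("P", [
            make_peak("c1", 9_990, 1.0, "P"),   # weakest -> rank 0
            make_peak("c1", 10_010, 9.0, "P"),  # strongest -> rank 1
            make_peak("c1", 700_000, 5.0, "P"),
        ])
        M = coloc.build_coloc_matrix(self.focus, [partner], GENES)
        assert M.matrix[0, 0] == 1.0

    def test_row_classes(self):
        M = coloc.build_coloc_matrix(self.focus, [], GENES)
        assert M.row_class == ["distal", "distal", "proximal"]

    def test_focus_among_partners_error(self):
        with pytest.raises(ValueError):
            coloc.build_coloc_matrix(self.focus, [PeakSet("F", [])], GENES)


class TestRandomizeMatrix:
    def test_column_multisets_preserved(self, rng):
        M = syn.synthesize_coloc_matrix(PARTNERS, PLANTED, n_rows=50, seed=1)
        for R in coloc.randomize_matrix(M, n=3, seed=2):
            for j in range(M.matrix.shape[1]):
                assert sorted(R[:, j]) == sorted(M.matrix[:, j])

    def test_joint_structure_destroyed(self):
        M = syn.synthesize_coloc_matrix(PARTNERS, PLANTED, n_rows=400, seed=3)
        [R] = coloc.randomize_matrix(M, n=1, seed=4)
        cols = [M.partners.index(p) for p in PLANTED]
        true_corr = np.corrcoef(M.matrix[:, cols].T)
        rand_corr = np.corrcoef(R[:, cols].T)
        off = ~np.eye(len(cols), dtype=bool)
        assert np.abs(true_corr[off]).mean() > 0.5
        assert np.abs(rand_corr[off]).mean() < 0.15

    def test_default_n(self):
        import inspect

        assert inspect.signature(coloc.randomize_matrix).parameters["n"].default == 10


@pytest.fixture(scope="module")
def planted_ensemble():
    M = syn.synthesize_coloc_matrix(PARTNERS, PLANTED, n_rows=400, seed=5)
    randomized = coloc.randomize_matrix(M, n=5, seed=6)
    return M, coloc.learn_rules(M, randomized, seed=7)


class TestLearnRules:
    def test_planted_dependency_high_auroc(self, planted_ensemble):
        _, ensemble = planted_ensemble
        assert ensemble.auroc >= 0.9

    def test_null_auroc_near_half(self):
        M = syn.synthesize_coloc_matrix(PARTNERS, PLANTED, n_rows=200, seed=8)
        [r1, r2] = coloc.randomize_matrix(M, n=2, seed=9)
        null_matrix = coloc.ColocMatrix(
            focus="null", partners=M.partners, matrix=r1,
            row_class=M.row_class,
        )
        ensemble = coloc.learn_rules(null_matrix, [r2], seed=10)
        assert 0.3 <= ensemble.auroc <= 0.7

    def test_rules_render_interval_form(self, planted_ensemble):
        _, ensemble = planted_ensemble
        assert ensemble.rules, "expected at least one retained rule"
        text = ensemble.rules[0].render()
        assert "<" in text and "<=" in text

    def test_single_column_error(self):
        M = coloc.ColocMatrix(focus="f", partners=["only"],
                              matrix=np.random.rand(10, 1),
                              row_class=["distal"] * 10)
        with pytest.raises(ValueError):
            coloc.learn_rules(M, [M.matrix.copy()])


class TestRelativeImportance:
    def test_planted_partner_ri_100(self, planted_ensemble):
        _, ensemble = planted_ensemble
        ri = coloc.relative_importance(ensemble)
        assert max(ri.values()) == 100.0
        assert max(ri, key=ri.get) in PLANTED

    def test_unused_partner_zero(self):
        ensemble = coloc.RuleEnsemble(
            focus="f", partners=["a", "b"],
            rules=[coloc.Rule(conditions=[("a", ">", 0.5)], coefficient=2.0,
                              support=0.4)],
            linear_coef=np.zeros(2), linear_scale=np.ones(2),
        )
        ri = coloc.relative_importance(ensemble)
        assert ri["b"] == 0.0 and ri["a"] == 100.0

    def test_all_zero_model(self):
        ensemble = coloc.RuleEnsemble(
            focus="f", partners=["a", "b"], rules=[],
            linear_coef=np.zeros(2), linear_scale=np.ones(2),
        )
        ri = coloc.relative_importance(ensemble)
        assert ri == {"a": 0.0, "b": 0.0}

    def test_column_order_invariance(self):
        M = syn.synthesize_coloc_matrix(PARTNERS, PLANTED, n_rows=200, seed=11)
        _, ri1 = coloc.context_importance(M, n_randomizations=3, seed=12)
        reordered = coloc.ColocMatrix(
            focus=M.focus, partners=M.partners[::-1],
            matrix=M.matrix[:, ::-1].copy(), row_class=M.row_class,
        )
        _, ri2 = coloc.context_importance(reordered, n_randomizations=3, seed=12)
        top1 = {p for p, v in ri1.items() if v > 50}
        top2 = {p for p, v in ri2.items() if v > 50}
        assert top1 & set(PLANTED) and top2 & set(PLANTED)


class TestDifferentialImportance:
    def test_proximal_only_partner_positive_di(self):
        M = syn.synthesize_coloc_matrix(
            PARTNERS, PLANTED, n_rows=500, proximal_only="T08", seed=13
        )
        di = coloc.differential_importance(M, n_randomizations=5, seed=14)
        assert di is not None
        assert di["T08"] > 0

    def test_small_subset_skipped_with_warning(self):
        M = syn.synthesize_coloc_matrix(
            PARTNERS, PLANTED, n_rows=40, proximal_fraction=0.1, seed=15
        )
        with pytest.warns(UserWarning):
            assert coloc.differential_importance(M) is None

    def test_absent_partner_average_zero(self):
        per_context = {"c1": {"a": 10.0}, "c2": {"a": 30.0}}
        avg = coloc.average_importance(per_context)
        assert avg["a"] == 20.0


class TestClusterRIMatrix:
    def test_duplicated_rows_adjacent(self, rng):
        base = rng.random((5, 6)) * 100
        ri = np.vstack([base, base[0]])
        names = [f"r{i}" for i in range(6)]
        out = coloc.cluster_ri_matrix(ri, names, [f"c{i}" for i in range(6)])
        order = out["row_order"]
        assert abs(order.index("r0") - order.index("r5")) == 1

    def test_planted_column_blocks(self, rng):
        block_a = np.tile([90.0, 80.0, 85.0], (6, 1))
        block_b = np.tile([5.0, 10.0, 2.0], (6, 1))
        ri = np.hstack([block_a, block_b]) + rng.random((6, 6))
        out = coloc.cluster_ri_matrix(
            ri, [f"r{i}" for i in range(6)],
            ["a1", "a2", "a3", "b1", "b2", "b3"],
        )
        labels = out["col_clusters"]
        assert len({labels["a1"], labels["a2"], labels["a3"]}) == 1
        assert len({labels["b1"], labels["b2"], labels["b3"]}) == 1
        assert labels["a1"] != labels["b1"]

    def test_deterministic(self, rng):
        ri = rng.random((5, 5)) * 100
        names = [f"x{i}" for i in range(5)]
        a = coloc.cluster_ri_matrix(ri, names, names)
        b = coloc.cluster_ri_matrix(ri, names, names)
        assert a["row_order"] == b["row_order"]
        assert a["col_clusters"] == b["col_clusters"]

    def test_too_small_error(self, rng):
        with pytest.raises(ValueError):
            coloc.cluster_ri_matrix(rng.random((2, 5)), ["a", "b"],
                                    list("cdefg"))
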