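"""Best-classifier search, Mann-Whitney testing, differential filtering."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from moanet import (
    BiomarkerRecord,
    MoAPointCloud,
    adjust_pvalues,
    best_classifiers,
    biomarker_report,
    differential_filter,
    filter_records,
    load_reference_biomarkers,
    mann_whitney,
    overrepresentation,
    read_gmt,
    reference_records,
)


def _cloud(matrix, start_id=0):
    m = np.asarray(matrix, dtype=float)
    return MoAPointCloud(
        ids=tuple(range(start_id, start_id + m.shape[0])),
        matrix=m,
        protein_order=tuple(f"P{i}" for i in range(m.shape[1])),
    )


class TestBestClassifiers:
    def test_perfect_separator_scores_one(self):
        a = _cloud([[0.5], [0.8], [0.3]])
        b = _cloud([[-0.5], [-0.2], [-0.9]], start_id=10)
        [cand] = best_classifiers(a, b, top_n=1)
        assert cand.classification_accuracy == 1.0
        assert cand.proteins == ("P0",)

    def test_identical_distributions_score_near_chance(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(20, 1))
        a = _cloud(vals[:10])
        b = _cloud(vals[10:], start_id=50)
        [cand] = best_classifiers(a, b, top_n=1)
        assert cand.classification_accuracy <= 0.75

    def test_constant_protein_scores_half_by_convention(self):
        a = _cloud([[1.0, 0.3], [1.0, 0.5]])
        b = _cloud([[1.0, -0.3], [1.0, -0.5]], start_id=10)
        cands = {c.proteins[0]: c for c in best_classifiers(a, b)}
        assert cands["P0"].classification_accuracy == 0.5
        assert cands["P1"].classification_accuracy == 1.0

    def test_ranking_matches_exhaustive_loo_oracle(self):
        rng = np.random.default_rng(1)
        A = rng.normal(0.3, 1.0, size=(6, 4))
        B = rng.normal(-0.3, 1.0, size=(6, 4))
        got = best_classifiers(_cloud(A), _cloud(B, start_id=10), top_n=4)

        def oracle_loo(x, y):
            # mirrors the documented tie-break: smallest threshold achieving
            # the best training accuracy; '+' orientation preferred on ties
            n = len(x)
            correct = 0
            for i in range(n):
                xt = np.delete(x, i)
                yt = np.delete(y, i)
                u = np.unique(xt)
                thrs = [u[0] - 1.0] + list((u[:-1] + u[1:]) / 2) + [u[-1] + 1.0]
                fits = {}
                for orient in (1, -1):
                    accs = [np.mean(((orient * (xt - t)) > 0) == (yt == 1)) for t in thrs]
                    k = int(np.argmax(accs))
                    fits[orient] = (accs[k], thrs[k])
                orient = 1 if fits[1][0] >= fits[-1][0] else -1
                thr = fits[orient][1]
                correct += int((orient * (x[i] - thr) > 0) == (y[i] == 1))
            return correct / n

        y = np.array([1] * 6 + [0] * 6)
        X = np.vstack([A, B])
        oracle = {f"P{j}": oracle_loo(X[:, j], y) for j in range(4)}
        for cand in got:
            p = cand.proteins[0]
            raw = oracle[p]
            assert cand.classification_accuracy == pytest.approx(max(raw, 1 - raw))

    def test_group_order_invariance_with_orientation_flip(self):
        rng = np.random.default_rng(2)
        A = rng.normal(0.5, 0.5, size=(5, 3))
        B = rng.normal(-0.5, 0.5, size=(5, 3))
        fwd = best_classifiers(_cloud(A), _cloud(B, start_id=10))
        rev = best_classifiers(_cloud(B, start_id=10), _cloud(A))
        assert [(c.proteins, round(c.classification_accuracy, 12)) for c in fwd] == [
            (c.proteins, round(c.classification_accuracy, 12)) for c in rev
        ]

    def test_pair_rules_can_beat_singles(self):
        # XOR-like layout: no single threshold separates, a conjunction does
        A = np.array([[0.8, 0.8], [0.6, 0.9], [0.9, 0.6]])
        B = np.array([[-0.8, 0.7], [0.7, -0.8], [-0.6, -0.7]])
        singles = best_classifiers(_cloud(A), _cloud(B, start_id=10))
        pairs = best_classifiers(_cloud(A), _cloud(B, start_id=10), include_pairs=True)
        best_single = max(c.classification_accuracy for c in singles)
        best_pair = max(
            c.classification_accuracy for c in pairs if len(c.proteins) == 2
        )
        assert best_pair >= best_single


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0]
        _, p = mann_whitney(a, list(a))
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_complete_separation_exact_p(self):
        a, b = [1.0, 2.0, 3.0, 4.0, 5.0], [6.0, 7.0, 8.0, 9.0, 10.0]
        u, p = mann_whitney(a, b)
        assert u == 0.0
        assert p == pytest.approx(2.0 / 252.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = list(np.round(rng.normal(size=6), 3))
        b = list(np.round(rng.normal(0.5, 1.0, size=5), 3))
        u_obs, p = mann_whitney(a, b)
        # oracle: enumerate all C(11, 6) group assignments of the pooled data
        pooled = a + b
        n = len(a)

        def ustat(group_a):
            group_b = [x for i, x in enumerate(pooled) if i not in set(group_a)]
            return sum(
                (pooled[i] > y) + 0.5 * (pooled[i] == y)
                for i in group_a for y in group_b
            )

        m = len(pooled) - n
        mid = n * m / 2
        count = total = 0
        for combo in itertools.combinations(range(len(pooled)), n):
            u = ustat(combo)
            total += 1
            if abs(u - mid) >= abs(u_obs - mid) - 1e-9:
                count += 1
        assert p == pytest.approx(count / total, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.03]) == [pytest.approx(0.03)]

    def test_equal_ps_stay_equal(self):
        out = adjust_pvalues([0.02] * 5)
        assert all(p == pytest.approx(0.02) for p in out)

    def test_hand_applied_step_up(self):
        out = adjust_pvalues([0.01, 0.02, 0.03, 0.04])
        assert out == [pytest.approx(0.04)] * 4

    def test_monotone_step_up_property(self):
        rng = np.random.default_rng(0)
        ps = rng.uniform(size=20)
        out = np.array(adjust_pvalues(list(ps)))
        order = np.argsort(ps)
        assert np.all(np.diff(out[order]) >= -1e-12)
        assert np.all(out >= ps - 1e-12)

    def test_bonferroni_and_validation(self):
        assert adjust_pvalues([0.01, 0.02], method="bonferroni") == [
            pytest.approx(0.02), pytest.approx(0.04)
        ]
        with pytest.raises(ValueError):
            adjust_pvalues([1.5])
        with pytest.raises(ValueError):
            adjust_pvalues([0.5], method="fancy")


class TestDifferentialFilter:
    def test_reference_table_partitions_sixteen_fourteen(self):
        records = reference_records()
        kept = filter_records(records, alpha=0.01)
        assert len(kept) == 30
        active = [r for r in kept if r.partition == "A-active/B-inactive"]
        inactive = [r for r in kept if r.partition == "A-inactive/B-active"]
        assert len(active) == 16 and len(inactive) == 14

    def test_zero_mean_excluded(self):
        r = BiomarkerRecord("X", 0.0, -0.5, 0.0, 1e-5, 1e-5)
        assert filter_records([r], alpha=0.01) == []

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(3)
        A = rng.normal(0.4, 0.6, size=(8, 6))
        B = rng.normal(-0.4, 0.6, size=(8, 6))
        ca, cb = _cloud(A), _cloud(B, start_id=20)
        cands = best_classifiers(ca, cb, top_n=6)
        got = {r.protein for r in differential_filter(cands, ca, cb, alpha=0.05)}
        praws = []
        for j in range(6):
            _, p = mann_whitney(A[:, j], B[:, j])
            praws.append(p)
        padj = adjust_pvalues(praws)
        brute = {
            f"P{j}"
            for j in range(6)
            if padj[j] < 0.05 and np.sign(A[:, j].mean()) == -np.sign(B[:, j].mean())
            and A[:, j].mean() != 0
        }
        assert got == brute

    def test_filter_output_is_subset_and_partitions_sum(self):
        records = reference_records()
        kept = filter_records(records, alpha=0.01)
        assert {r.protein for r in kept} <= {r.protein for r in records}
        a = sum(r.partition == "A-active/B-inactive" for r in kept)
        b = sum(r.partition == "A-inactive/B-active" for r in kept)
        assert a + b == len(kept)


class TestReport:
    def test_empty_records_give_header_only(self):
        df = biomarker_report([])
        assert len(df) == 0
        assert list(df.columns)[:3] == ["protein", "mean_A", "mean_B"]

    def test_fibrinogen_row_orientation(self):
        rec = next(r for r in reference_records() if r.protein == "FGB")
        assert rec.mean_a == pytest.approx(-0.576)
        assert rec.mean_b == pytest.approx(0.814)
        assert rec.partition == "A-inactive/B-active"

    def test_membership_annotation(self):
        recs = [
            BiomarkerRecord("X", 0.5, -0.5, 0.25, 1e-4, 1e-3),
            BiomarkerRecord("Y", -0.5, 0.5, 0.25, 1e-4, 1e-3),
        ]
        df = biomarker_report(recs, bcp_sets={"HF": {"X"}, "MD": {"X", "Y"}})
        by = dict(zip(df["protein"], df["bcp"]))
        assert by == {"X": "HF&MD", "Y": "MD"}

    def test_sorted_by_strength(self):
        df = biomarker_report(reference_records())
        assert list(df["strength"]) == sorted(df["strength"], reverse=True)

    def test_reference_table_shape(self):
        df = load_reference_biomarkers()
        assert len(df) == 30
        assert df["p_adjusted"].max() < 0.01


class TestOverrepresentation:
    def test_self_set_is_maximally_enriched(self):
        genes = {f"g{i}" for i in range(10)}
        background = genes | {f"h{i}" for i in range(10)}
        df = overrepresentation(genes, {"self": set(genes)}, background)
        row = df.iloc[0]
        assert row["p"] < 0.05 and row["lod"] > 1

    def test_disjoint_set_has_low_odds(self):
        genes = {f"g{i}" for i in range(5)}
        other = {f"h{i}" for i in range(5)}
        background = genes | other | {f"x{i}" for i in range(20)}
        df = overrepresentation(genes, {"other": other}, background)
        assert df.iloc[0]["odds_ratio"] <= 1

    def test_fisher_matches_hypergeometric_sum(self):
        # 2x2 table (5,5,5,85): P(X >= 5) with N=100, K=10 marked, n=10 drawn
        genes = {f"g{i}" for i in range(10)}
        marked = {f"g{i}" for i in range(5)} | {f"m{i}" for i in range(5)}
        background = genes | marked | {f"b{i}" for i in range(85)}
        df = overrepresentation(genes, {"s": marked}, background)
        oracle = sum(
            math.comb(10, k) * math.comb(90, 10 - k) / math.comb(100, 10)
            for k in range(5, 11)
        )
        assert df.iloc[0]["p"] == pytest.approx(oracle, rel=1e-9)

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValueError):
            overrepresentation({"a"}, {"s": {"a"}}, {"b"})

    def test_gmt_round_trip(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("setA\tdesc\tg1\tg2\nsetB\tdesc\tg3\n")
        sets = read_gmt(p)
        assert sets == {"setA": {"g1", "g2"}, "setB": {"g3"}}
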