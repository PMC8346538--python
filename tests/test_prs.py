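"""C+T PRS: clumping, model building, scoring and threshold selection."""

import math

import numpy as np
import pandas as pd
import pytest

from prstrat.cohort import AssocResult, GenotypeMatrix, SampleInfo, VariantInfo
from prstrat.evaluate import auc
from prstrat.prs import (
    CTPRS,
    DEFAULT_GRID,
    PRSModel,
    build_model,
    clump,
    score,
    select_p_threshold,
)


def make_results(specs):
    """specs: list of (id, chrom, pos, p, beta)."""
    out = []
    for vid, chrom, pos, p, beta in specs:
        v = VariantInfo(chrom=chrom, pos=pos, id=vid, effect_allele="A",
                        other_allele="G", maf=0.2)
        out.append(AssocResult.from_fit(v, "A", 100, beta, 0.1, p))
    return out


def matrix_from(dosages, specs):
    dosages = np.asarray(dosages, dtype=float)
    samples = [SampleInfo(f"s{i}") for i in range(dosages.shape[0])]
    variants = [
        VariantInfo(chrom=chrom, pos=pos, id=vid, effect_allele="A",
                    other_allele="G", maf=0.2)
        for vid, chrom, pos, *_ in specs
    ]
    return GenotypeMatrix(dosages, samples, variants)


class TestClump:
    def test_perfect_proxy_keeps_smaller_p(self):
        specs = [("a", "1", 10_000, 1e-10, 0.5), ("b", "1", 20_000, 1e-9, 0.5)]
        rng = np.random.default_rng(0)
        col = rng.binomial(2, 0.3, 100).astype(float)
        G = matrix_from(np.column_stack([col, col]), specs)
        assert clump(make_results(specs), G, 0.1, 250.0) == ["a"]

    def test_different_chromosomes_all_kept(self):
        specs = [("a", "1", 10_000, 1e-10, 0.5), ("b", "2", 10_000, 1e-9, 0.5)]
        rng = np.random.default_rng(0)
        col = rng.binomial(2, 0.3, 100).astype(float)
        G = matrix_from(np.column_stack([col, col]), specs)
        assert set(clump(make_results(specs), G, 0.1, 250.0)) == {"a", "b"}

    def test_outside_window_kept(self):
        specs = [("a", "1", 10_000, 1e-10, 0.5), ("b", "1", 400_000, 1e-9, 0.5)]
        rng = np.random.default_rng(0)
        col = rng.binomial(2, 0.3, 100).astype(float)
        G = matrix_from(np.column_stack([col, col]), specs)
        assert set(clump(make_results(specs), G, 0.1, 250.0)) == {"a", "b"}

    def test_matches_brute_force_greedy(self):
        # 20 variants in correlated blocks: compare against a reference that
        # re-scans the full list each round
        rng = np.random.default_rng(42)
        n = 300
        base = rng.binomial(2, 0.3, size=(n, 4)).astype(float)
        cols, specs = [], []
        for j in range(20):
            block = j % 4
            noisy = base[:, block].copy()
            flip = rng.random(n) < 0.15
            noisy[flip] = rng.binomial(2, 0.3, flip.sum())
            cols.append(noisy)
            specs.append((f"v{j}", "1", 10_000 + 5_000 * j,
                          float(rng.uniform(1e-12, 1e-2)), 0.3))
        G = matrix_from(np.column_stack(cols), specs)
        results = make_results(specs)
        got = clump(results, G, r2_threshold=0.4, window_kb=250.0)

        # brute-force oracle
        X = np.column_stack(cols)
        order = sorted(range(20), key=lambda i: (specs[i][3], specs[i][2]))
        idx_of = {f"v{j}": j for j in range(20)}
        claimed, kept = set(), []
        for i in order:
            if i in claimed:
                continue
            kept.append(f"v{i}")
            claimed.add(i)
            for j in order:
                if j in claimed or abs(specs[j][2] - specs[i][2]) > 250_000:
                    continue
                r = np.corrcoef(X[:, i], X[:, j])[0, 1] ** 2
                if r > 0.4:
                    claimed.add(j)
        assert got == kept

    def test_absent_variant_excluded_with_warning(self):
        specs = [("a", "1", 10_000, 1e-10, 0.5)]
        G = matrix_from(np.zeros((10, 1)) + 1.0, specs)
        extra = make_results(specs + [("zz", "3", 5_000, 1e-5, 0.2)])
        with pytest.warns(UserWarning, match="absent"):
            kept = clump(extra, G, 0.1, 250.0)
        assert kept == ["a"]


class TestBuildModel:
    def test_nested_thresholds(self):
        specs = [(f"v{i}", "1", 10_000 * (i + 1), p, 0.3)
                 for i, p in enumerate([1e-12, 1e-8, 1e-4, 0.03, 0.5])]
        results = make_results(specs)
        ids = [s[0] for s in specs]
        previous = set()
        for thr in DEFAULT_GRID:
            try:
                m = build_model(results, ids, thr)
            except ValueError:
                continue
            entries = set(m.entries["variant_id"])
            assert previous.issubset(entries)
            previous = entries
        assert previous == set(ids)  # threshold 1 includes everything

    def test_beta_is_log_or(self):
        specs = [("a", "1", 10_000, 1e-10, math.log(2.0))]
        m = build_model(make_results(specs), ["a"], 1.0)
        assert m.entries["beta"].iloc[0] == pytest.approx(math.log(2.0))

    def test_empty_model_errors_with_threshold(self):
        specs = [("a", "1", 10_000, 0.5, 0.3)]
        with pytest.raises(ValueError, match="1e-10"):
            build_model(make_results(specs), ["a"], 1e-10)


class TestScore:
    def one_variant_model(self, beta=0.5):
        return PRSModel(
            pd.DataFrame([{"variant_id": "a", "effect_allele": "A",
                           "beta": beta, "train_p": 1e-9}]),
            p_threshold=1e-8, clump_params=(0.1, 250.0),
        )

    def test_single_variant_arithmetic(self):
        G = matrix_from(np.array([[2.0]]), [("a", "1", 100, 0, 0)])
        s = score(self.one_variant_model(0.5), G)
        assert s.scores[0] == pytest.approx(0.5 * 2 / (2 * 1))

    def test_zero_dosages_zero_score(self):
        G = matrix_from(np.zeros((3, 1)), [("a", "1", 100, 0, 0)])
        np.testing.assert_allclose(score(self.one_variant_model(), G).scores, 0.0)

    def test_missing_dosage_average_per_allele(self):
        specs = [(f"v{i}", "1", 100 * (i + 1), 0, 0) for i in range(5)]
        betas = [0.1, 0.2, -0.3, 0.4, 0.25]
        model = PRSModel(
            pd.DataFrame(
                [{"variant_id": f"v{i}", "effect_allele": "A", "beta": b,
                  "train_p": 1e-9} for i, b in enumerate(betas)]
            ),
            p_threshold=1e-8, clump_params=(0.1, 250.0),
        )
        dos = np.array([[1.0, 2.0, np.nan, 0.0, 1.0]])
        G = matrix_from(dos, specs)
        s = score(model, G)
        expected = (0.1 * 1 + 0.2 * 2 + 0.4 * 0 + 0.25 * 1) / (2 * 4)
        assert s.scores[0] == pytest.approx(expected)
        assert s.m_used[0] == 4

    def test_linearity_in_betas(self):
        rng = np.random.default_rng(3)
        specs = [(f"v{i}", "1", 100 * (i + 1), 0, 0) for i in range(4)]
        G = matrix_from(rng.binomial(2, 0.3, size=(20, 4)).astype(float), specs)
        entries = pd.DataFrame(
            [{"variant_id": f"v{i}", "effect_allele": "A",
              "beta": float(rng.normal()), "train_p": 1e-9} for i in range(4)]
        )
        m1 = PRSModel(entries, 1e-8, (0.1, 250.0))
        m2 = PRSModel(entries.assign(beta=entries["beta"] * 2), 1e-8, (0.1, 250.0))
        np.testing.assert_allclose(score(m2, G).scores, 2 * score(m1, G).scores,
                                   atol=1e-12)

    def test_allele_flip_offsets_by_beta_over_m(self):
        # representing (beta, A1) as (-beta, A2) shifts each score by exactly
        # -beta / M_j after the dosage flip
        rng = np.random.default_rng(9)
        specs = [(f"v{i}", "1", 100 * (i + 1), 0, 0) for i in range(3)]
        G = matrix_from(rng.binomial(2, 0.4, size=(10, 3)).astype(float), specs)
        entries = pd.DataFrame(
            [{"variant_id": f"v{i}", "effect_allele": "A", "beta": b,
              "train_p": 1e-9} for i, b in enumerate([0.2, -0.1, 0.5])]
        )
        flipped = entries.copy()
        flipped.loc[0, "effect_allele"] = "G"
        flipped.loc[0, "beta"] = -0.2
        s_orig = score(PRSModel(entries, 1e-8, (0.1, 250.0)), G)
        s_flip = score(PRSModel(flipped, 1e-8, (0.1, 250.0)), G)
        np.testing.assert_allclose(
            s_flip.scores - s_orig.scores, -0.2 / s_orig.m_used, atol=1e-12
        )

    def test_unmatched_variants_counted_all_absent_errors(self):
        G = matrix_from(np.array([[1.0]]), [("a", "1", 100, 0, 0)])
        model = PRSModel(
            pd.DataFrame([
                {"variant_id": "a", "effect_allele": "A", "beta": 0.5, "train_p": 1e-9},
                {"variant_id": "qq", "effect_allele": "A", "beta": 0.5, "train_p": 1e-9},
            ]),
            1e-8, (0.1, 250.0),
        )
        s = score(model, G)
        assert s.n_unmatched == 1
        only_missing = PRSModel(model.entries.iloc[[1]], 1e-8, (0.1, 250.0))
        with pytest.raises(ValueError, match="matched"):
            score(only_missing, G)


class TestSelectThreshold:
    def test_grid_of_one_returns_it(self):
        specs = [("a", "1", 10_000, 1e-10, 0.6)]
        rng = np.random.default_rng(1)
        col = rng.binomial(2, 0.3, 60).astype(float)
        G = matrix_from(col.reshape(-1, 1), specs)
        y = (col + rng.normal(0, 1, 60) > 0.8).astype(int)
        best, table = select_p_threshold(make_results(specs), G, G, y, grid=[1e-5])
        assert best == 1e-5 and len(table) == 1

    def test_shuffled_labels_give_null_aucs(self):
        rng = np.random.default_rng(7)
        specs = [(f"v{i}", "1", 10_000 * (i + 1), p, 0.4)
                 for i, p in enumerate([1e-10, 1e-6, 1e-3])]
        G = matrix_from(rng.binomial(2, 0.3, size=(400, 3)).astype(float), specs)
        y = rng.integers(0, 2, 400)  # independent of genotypes
        n1, n0 = int(y.sum()), int((1 - y).sum())
        se = math.sqrt((1 / n1 + 1 / n0) / 12)
        _, table = select_p_threshold(make_results(specs), G, G, y)
        aucs = table["auc"].dropna()
        assert ((aucs - 0.5).abs() < 3 * se).all()

    def test_signal_gives_informative_auc(self, small_cohort):
        from prstrat.assoc import gwas
        from prstrat.cohort import split_cohorts

        G, samples, *_ = small_cohort
        a, b = split_cohorts(samples, seed=1)
        ids_a = {s.sample_id for s in a}
        mask = np.array([s.sample_id in ids_a for s in G.samples])
        G_train, G_test = G.subset_samples(mask), G.subset_samples(~mask)
        train_results, _ = gwas(G_train)
        y = G_test.phenotype_array()
        n1, n0 = int(y.sum()), int((1 - y).sum())
        se = math.sqrt((1 / n1 + 1 / n0) / 12)
        best, table = select_p_threshold(train_results, G_train, G_test)
        assert len(table) == len(DEFAULT_GRID)
        assert table["auc"].max() > 0.5 + 5 * se
        best_row = table.loc[table["auc"].idxmax()]
        assert best == best_row["p_threshold"]


class TestCTPRSEstimator:
    def test_sklearn_params_round_trip(self):
        est = CTPRS(p_threshold=1e-5, clump_r2=0.2)
        assert est.get_params()["clump_r2"] == 0.2
        est.set_params(clump_window_kb=100.0)
        assert est.clump_window_kb == 100.0

    def test_fit_select_score_predict(self, small_cohort):
        from prstrat.cohort import split_cohorts

        G, samples, *_ = small_cohort
        a, _ = split_cohorts(samples, seed=2)
        ids_a = {s.sample_id for s in a}
        mask = np.array([s.sample_id in ids_a for s in G.samples])
        G_train, G_test = G.subset_samples(mask), G.subset_samples(~mask)
        est = CTPRS().fit(G_train)
        est.select_threshold(G_test)
        s = est.decision_function(G_test)
        assert s.shape == (G_test.n_samples,)
        assert auc(s, G_test.phenotype_array()) > 0.6
        est.fit_cutoff(G_test)
        pred = est.predict(G_test)
        assert set(np.unique(pred)) <= {0, 1}
        # MCC-optimal rule: prediction equals score > cutoff
        np.testing.assert_array_equal(pred, (s > est.cutoff_).astype(int))

    def test_unfitted_errors(self, small_cohort):
        G, *_ = small_cohort
        with pytest.raises(ValueError, match="not fitted"):
            CTPRS().decision_function(G)
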