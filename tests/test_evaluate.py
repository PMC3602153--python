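"""Metrics, ROC/PR oracles, and cross-validation partition contracts."""
import numpy as np
import pytest
from scipy.stats import rankdata

from pdzscan import evaluate
from pdzscan.evaluate import (
    EvaluationError,
    compute_metrics,
    cv_long_table,
    domain_similarity,
    roc_pr_auc,
    run_cv,
    similarity_filtered_cv,
    _domain_holdout_split,
)
from pdzscan.training import InteractionRecord


class TestMetrics:
    def test_formula_instantiation(self):
        labels = [1, 1, 1, 1, -1, -1]
        preds = [1, 1, 1, -1, -1, 1]
        m = compute_metrics(labels, preds)
        assert m.sensitivity == pytest.approx(3 / 4)
        assert m.specificity == pytest.approx(1 / 2)
        assert m.precision == pytest.approx(3 / 4)

    def test_undefined_precision_flagged_not_zero(self):
        m = compute_metrics([1, 1, -1], [-1, -1, -1])
        assert m.precision is None
        assert m.sensitivity == 0.0

    def test_perfect_predictor(self):
        m = compute_metrics([1, -1, 1], [1, -1, 1])
        assert (m.sensitivity, m.specificity, m.precision) == (1.0, 1.0, 1.0)

    def test_length_mismatch(self):
        with pytest.raises(EvaluationError):
            compute_metrics([1, -1], [1])


class TestAUC:
    def test_perfect_separation(self):
        roc, pr = roc_pr_auc([1, 1, -1, -1], [1.0, 0.9, -0.8, -1.0])
        assert roc == 1.0 and pr == 1.0

    def test_random_scores_null_expectations(self):
        rng = np.random.default_rng(123)
        n = 10000
        labels = np.where(rng.random(n) < 0.3, 1, -1)
        scores = rng.normal(size=n)
        roc, pr = roc_pr_auc(labels, scores)
        assert roc == pytest.approx(0.5, abs=0.02)
        # a random scorer's PR AUC equals the positive fraction
        assert pr == pytest.approx(np.mean(labels == 1), abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            roc_pr_auc([1, 1], [0.2, 0.3])

    def test_equals_mann_whitney_u(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n_pos = rng.integers(2, 10)
            n_neg = rng.integers(2, 10)
            labels = np.array([1] * n_pos + [-1] * n_neg)
            scores = rng.normal(size=n_pos + n_neg)
            roc, _ = roc_pr_auc(labels, scores)
            # independent oracle: U statistic from midranks
            ranks = rankdata(scores)
            u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
            assert roc == pytest.approx(u / (n_pos * n_neg), abs=1e-9)


class TestDomainSimilarity:
    def test_identity_and_half(self):
        assert domain_similarity("LGIRESFGHA", "LGIRESFGHA") == 1.0
        assert domain_similarity("AAAAABBBBB", "AAAAACCCCC") == 0.5

    def test_permutation_invariance(self):
        a, b = "LGIRESFGHA", "LGIRESAAAA"
        perm = np.random.default_rng(0).permutation(10)
        ap = "".join(a[i] for i in perm)
        bp = "".join(b[i] for i in perm)
        assert domain_similarity(a, b) == domain_similarity(ap, bp)

    def test_length_mismatch(self):
        with pytest.raises(EvaluationError):
            domain_similarity("AB", "ABC")


class TestHoldoutPartitions:
    def _fake_records(self, n_domains=100, per_domain=5):
        return [InteractionRecord(f"d{i}", "RETQV", +1)
                for i in range(n_domains) for _ in range(per_domain)]

    def test_twelve_percent_of_domains_held_out(self):
        records = self._fake_records(100)
        rng = np.random.default_rng(0)
        train_idx, test_idx = _domain_holdout_split(records, rng,
                                                    domain_frac=0.12)
        test_domains = {records[i].domain_id for i in test_idx}
        train_domains = {records[i].domain_id for i in train_idx}
        assert len(test_domains) == 12
        assert not test_domains & train_domains
        assert len(train_idx) + len(test_idx) == len(records)

    def test_peptide_holdout_respects_fraction(self):
        records = [InteractionRecord("d", p, +1) for p in
                   {"RETQV", "AAAAA", "CCCCC", "DDDDD", "EEEEE", "FFFFF",
                    "GGGGG", "HHHHH", "IIIII", "KKKKK", "LLLLL", "MMMMM",
                    "NNNNN", "PPPPP", "QQQQQ", "RRRRR", "SSSSS", "TTTTT",
                    "VVVVV", "WWWWW", "YYYYY", "WWWWY", "YYYYW", "WYWYW",
                    "YWYWY"}]
        rng = np.random.default_rng(1)
        train_idx, test_idx = _domain_holdout_split(records, rng,
                                                    peptide_frac=0.08)
        test_peps = {records[i].peptide for i in test_idx}
        assert len(test_peps) == max(1, round(0.08 * len(records)))
        assert not test_peps & {records[i].peptide for i in train_idx}


class TestRunCV:
    def test_tenfold_partition_contract(self, small_data):
        records = small_data["records"]
        res = run_cv(records, small_data["vectors"], scheme="tenfold",
                     gamma=0.01, c_negative=4.0, seed=0)
        all_test = np.concatenate([f.test_indices for f in res.folds])
        assert sorted(all_test) == list(range(len(records)))
        sizes = {len(f.test_indices) for f in res.folds}
        assert max(sizes) - min(sizes) <= 1

    def test_leave_domains_no_domain_leakage(self, small_data):
        records = small_data["records"]
        res = run_cv(records, small_data["vectors"], scheme="leave_domains",
                     repeats=4, gamma=0.01, c_negative=4.0, seed=0)
        for fold in res.folds:
            test_domains = {records[i].domain_id for i in fold.test_indices}
            train_domains = {records[i].domain_id
                             for i in range(len(records))
                             if i not in set(fold.test_indices)}
            assert not test_domains & train_domains

    def test_planted_signal_recovered_and_permuted_null(self, small_data):
        records = small_data["records"]
        res = run_cv(records, small_data["vectors"], scheme="tenfold",
                     gamma=0.01, c_negative=4.0, seed=0)
        assert res.mean_roc_auc >= 0.9
        rng = np.random.default_rng(99)
        labels = rng.permutation([r.label for r in records])
        permuted = [InteractionRecord(r.domain_id, r.peptide, int(l), r.source)
                    for r, l in zip(records, labels)]
        null = run_cv(permuted, small_data["vectors"], scheme="tenfold",
                      gamma=0.01, c_negative=4.0, seed=0)
        # small-sample null is noisy; the tight null check runs on the
        # full-size fixture conditions in the acceptance suite
        assert null.pooled_auc()[0] == pytest.approx(0.5, abs=0.2)
        assert null.mean_roc_auc < res.mean_roc_auc - 0.2

    def test_long_table_export(self, small_data):
        res = run_cv(small_data["records"], small_data["vectors"],
                     scheme="tenfold", gamma=0.01, c_negative=4.0, seed=0)
        df = cv_long_table(res)
        assert len(df) == 10
        assert {"scheme", "fold", "roc_auc", "pr_auc"} <= set(df.columns)


class TestSimilarityFilteredCV:
    def test_degenerate_threshold_matches_plain_leave_domains(self, small_data):
        records = small_data["records"]
        vectors = small_data["vectors"]
        plain = run_cv(records, vectors, scheme="leave_domains", repeats=3,
                       gamma=0.01, c_negative=4.0, seed=0)
        filtered = similarity_filtered_cv(
            records, vectors, small_data["site_seqs"], thresholds=[1.01],
            folds=3, repeats=1, gamma=0.01, c_negative=4.0, seed=0)[1.01]
        for f_plain, f_filt in zip(plain.folds, filtered.folds):
            assert np.array_equal(f_plain.test_indices, f_filt.test_indices)
            assert f_plain.n_train == f_filt.n_train

    def test_threshold_below_min_similarity_all_missing(self, small_data):
        out = similarity_filtered_cv(
            small_data["records"], small_data["vectors"],
            small_data["site_seqs"], thresholds=[-0.1], folds=2, repeats=1,
            gamma=0.01, c_negative=4.0, seed=0)
        assert all(f.missing for f in out[-0.1].folds)

    def test_interaction_cap_respected(self, small_data):
        out = similarity_filtered_cv(
            small_data["records"], small_data["vectors"],
            small_data["site_seqs"], thresholds=[1.01], folds=2, repeats=1,
            max_train=100, gamma=0.01, c_negative=4.0, seed=0)
        for fold in out[1.01].folds:
            if not fold.missing:
                assert fold.n_train <= 100

    def test_cross_cluster_generalization_is_harder(self, small_data):
        """Domains form two archetype clusters; excluding same-cluster
        training domains must lower the achievable AUC."""
        out = similarity_filtered_cv(
            small_data["records"], small_data["vectors"],
            small_data["site_seqs"], thresholds=[1.01, 0.5], folds=4,
            repeats=1, gamma=0.01, c_negative=4.0, seed=0)
        assert out[0.5].mean_roc_auc < out[1.01].mean_roc_auc
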