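import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from ncproj.data import ValidationError
from ncproj.evaluation import (
    isolated_disease_eval,
    loocv,
    pr_aupr,
    rank_unknown,
    roc_auc,
    run_ablations,
)
from ncproj.projection import epsilon_substitute, score_dataset
from ncproj.similarity import IntegrationConfig
from ncproj.synthetic import generate, separable_params
from tests.conftest import random_dataset


def mann_whitney_auc(pos, neg):
    """Exhaustive pairwise P(pos > neg) + 0.5 P(pos = neg)."""
    pos = np.asarray(pos)
    neg = np.asarray(neg)
    wins = sum(
        1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


def grouped_pr_oracle(pos, neg):
    """Precision/recall by explicit threshold grouping, trapezoid AUPR."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    thresholds = sorted(set(pos) | set(neg), reverse=True)
    recalls, precisions = [0.0], []
    tp0 = np.sum(pos >= thresholds[0])
    fp0 = np.sum(neg >= thresholds[0])
    precisions.append(tp0 / (tp0 + fp0) if tp0 + fp0 else 1.0)
    for t in thresholds:
        tp = np.sum(pos >= t)
        fp = np.sum(neg >= t)
        recalls.append(tp / len(pos))
        precisions.append(tp / (tp + fp))
    return float(np.trapezoid(precisions, recalls))


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.9, 0.8], [0.2, 0.1])
        assert auc == 1.0

    def test_all_ties_give_half(self):
        _, auc = roc_auc([0.5, 0.5], [0.5, 0.5, 0.5])
        assert auc == pytest.approx(0.5, abs=1e-15)

    def test_curve_endpoints(self):
        curve, _ = roc_auc([0.9, 0.4], [0.5, 0.1])
        assert (curve.x[0], curve.y[0]) == (0.0, 0.0)
        assert (curve.x[-1], curve.y[-1]) == (1.0, 1.0)
        assert np.all(np.diff(curve.x) >= 0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_mann_whitney_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # coarse grid forces plenty of duplicate scores
        pos = rng.choice(np.linspace(0, 1, 20), size=50)
        neg = rng.choice(np.linspace(0, 1, 20), size=70)
        _, auc = roc_auc(pos, neg)
        assert auc == pytest.approx(mann_whitney_auc(pos, neg), abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_sklearn(self, seed):
        rng = np.random.default_rng(50 + seed)
        pos = rng.random(40)
        neg = rng.random(60)
        _, auc = roc_auc(pos, neg)
        y = np.concatenate([np.ones(40), np.zeros(60)])
        s = np.concatenate([pos, neg])
        assert auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValidationError, match="non-empty"):
            roc_auc([], [0.1])


class TestPrAupr:
    def test_perfect(self):
        _, aupr = pr_aupr([0.9], [0.1])
        assert aupr == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_grouped_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.choice(np.linspace(0, 1, 15), size=30)
        neg = rng.choice(np.linspace(0, 1, 15), size=60)
        _, aupr = pr_aupr(pos, neg)
        assert aupr == pytest.approx(grouped_pr_oracle(pos, neg), abs=1e-12)

    def test_null_pools_approach_prevalence(self):
        # identically distributed pools at 1:9 ratio: AUPR ~ prevalence
        rng = np.random.default_rng(0)
        auprs = []
        for _ in range(10):
            scores = rng.random(5000)
            auprs.append(pr_aupr(scores[:500], scores[500:])[1])
        assert np.mean(auprs) == pytest.approx(0.1, abs=0.05)

    def test_empty_positive_pool_rejected(self):
        with pytest.raises(ValidationError, match="positive"):
            pr_aupr([], [0.1])


class TestLoocv:
    def test_one_fold_per_association(self, small_dataset):
        result = loocv(small_dataset)
        assert result.n_folds == small_dataset.as_matrix.n_associations
        assert len(result.pooled_positive_scores) == result.n_folds

    def test_fold_isolation_restores_full_scores(self, small_dataset):
        # mutating a fold and restoring it must reproduce the full-data
        # model bitwise: no state leaks between folds
        before = score_dataset(small_dataset).values.copy()
        loocv(small_dataset)
        after = score_dataset(small_dataset).values
        assert np.array_equal(before, after)

    def test_sole_association_disease_scores_finite(self):
        ds = random_dataset(seed=21, n_mirna=6, n_disease=4)
        values = ds.as_matrix.values.copy()
        # make d0 depend on a single association
        values[:, 0] = 0
        values[0, 0] = 1
        ds = ds.replace_associations(values)
        result = loocv(ds)
        assert np.all(np.isfinite(result.pooled_positive_scores))

    def test_separable_dataset_perfect_auc(self):
        ds, _ = generate(separable_params(seed=0))
        result = loocv(ds)
        assert result.auc == 1.0
        assert all(rec.rank == 1.0 for rec in result.fold_records)

    def test_shared_negatives_approximation_close(self):
        ds = random_dataset(seed=13, n_mirna=10, n_disease=6)
        faithful = loocv(ds)
        fast = loocv(ds, shared_negatives=True)
        assert fast.n_folds == faithful.n_folds
        assert abs(fast.auc - faithful.auc) < 0.1

    def test_too_few_associations_rejected(self):
        ds = random_dataset(seed=1, n_mirna=4, n_disease=3)
        values = np.zeros_like(ds.as_matrix.values)
        values[0, 0] = 1
        with pytest.raises(ValidationError, match="at least 2"):
            loocv(ds.replace_associations(values))


class TestRunAblations:
    def test_no_sn_tag_equals_explicit_config(self, small_dataset):
        results = run_ablations(small_dataset, tags=("no_sn",))
        direct = loocv(
            small_dataset, IntegrationConfig(use_sn=False), "combined"
        )
        assert results["no_sn"].auc == direct.auc
        assert np.array_equal(
            results["no_sn"].pooled_positive_scores,
            direct.pooled_positive_scores,
        )

    def test_all_tags_separable_above_09(self):
        ds, _ = generate(separable_params(seed=1))
        results = run_ablations(ds)
        for tag, r in results.items():
            assert r.auc > 0.9, tag

    def test_identical_fold_order_across_tags(self, small_dataset):
        results = run_ablations(small_dataset, tags=("full", "no_sn"))
        full_pairs = [
            (r.mirna, r.disease) for r in results["full"].fold_records
        ]
        nosn_pairs = [
            (r.mirna, r.disease) for r in results["no_sn"].fold_records
        ]
        assert full_pairs == nosn_pairs

    def test_mirna_space_positives_equal_cosine(self, small_dataset):
        # per fold, the single-space positive score is the plain cosine of
        # the SM row and the fold's association column
        results = run_ablations(small_dataset, tags=("mirna_space",))
        cfg = IntegrationConfig()
        for rec in results["mirna_space"].fold_records[:5]:
            i = small_dataset.mirna_index.position(rec.mirna)
            j = small_dataset.disease_index.position(rec.disease)
            values = small_dataset.as_matrix.values.copy()
            values[i, j] = 0
            fold_ds = small_dataset.replace_associations(values)
            from ncproj.similarity import (
                integrate_mirna_similarity,
                profile_jaccard,
            )

            ncm = profile_jaccard(fold_ds.as_matrix, "mirna", cfg.epsilon)
            sm = integrate_mirna_similarity(
                fold_ds.mm, ncm, fold_ds.fam, cfg
            ).values
            as_eps = epsilon_substitute(fold_ds.as_matrix.values, cfg.epsilon)
            u, v = sm[i], as_eps[:, j]
            cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            assert rec.score == pytest.approx(cos, abs=1e-12)


class TestIsolatedDisease:
    def test_blinded_column_finite_and_nonzero(self, small_dataset):
        disease = small_dataset.disease_index.labels[0]
        result = isolated_disease_eval(small_dataset, disease)
        scores = [r.score for r in result.records]
        assert all(np.isfinite(s) for s in scores)
        assert any(s > 0 for s in scores)

    def test_recovers_planted_associations(self):
        ds, _ = generate(separable_params(seed=2))
        col_sums = ds.as_matrix.values.sum(axis=0)
        disease = ds.disease_index.labels[int(np.argmax(col_sums))]
        result = isolated_disease_eval(ds, disease)
        assert result.mean_rank_percentile < 0.5

    def test_twin_diseases_get_identical_rankings(self):
        # two diseases indistinguishable to the model (same SD column and
        # same associations elsewhere) must rank miRNAs identically when
        # blinded
        ds = random_dataset(seed=30, n_mirna=6, n_disease=4, with_family=False)
        dd = ds.dd.values.copy()
        dd[:, 1] = dd[:, 0]
        dd[1, :] = dd[0, :]
        dd[0, 1] = dd[1, 0] = 1.0  # keep symmetry; d0 and d1 now twins
        as_values = ds.as_matrix.values.copy()
        as_values[:, 1] = as_values[:, 0]
        from ncproj.data import AssociationMatrix, Dataset, SimilarityMatrix

        ds2 = Dataset(
            mm=ds.mm,
            dd=SimilarityMatrix(ds.dd.index, dd, "DD"),
            as_matrix=AssociationMatrix(
                ds.mirna_index, ds.disease_index, as_values
            ),
        )
        cfg = IntegrationConfig(use_sn=False)
        r0 = isolated_disease_eval(ds2, ds2.disease_index.labels[0], cfg)
        r1 = isolated_disease_eval(ds2, ds2.disease_index.labels[1], cfg)
        assert [r.mirna for r in r0.records] == [r.mirna for r in r1.records]

    def test_unknown_disease_rejected(self, small_dataset):
        with pytest.raises(ValidationError, match="unknown disease"):
            isolated_disease_eval(small_dataset, "nope")


class TestRankUnknown:
    def test_known_pairs_excluded(self, small_dataset):
        records = rank_unknown(small_dataset, top_k=10**6)
        known = set(small_dataset.as_matrix.pairs())
        assert all((r.mirna, r.disease) not in known for r in records)

    def test_truncation_beyond_unknown_count(self, small_dataset):
        n_unknown = int((small_dataset.as_matrix.values == 0).sum())
        records = rank_unknown(small_dataset, top_k=n_unknown + 100)
        assert len(records) == n_unknown

    def test_hidden_separable_pair_ranks_first(self):
        ds, _ = generate(separable_params(seed=3))
        values = ds.as_matrix.values.copy()
        i, j = np.argwhere(values == 1)[0]
        values[i, j] = 0
        hidden_ds = ds.replace_associations(values)
        records = rank_unknown(hidden_ds, top_k=1)
        assert (records[0].mirna, records[0].disease) == (
            ds.mirna_index.labels[i],
            ds.disease_index.labels[j],
        )

    def test_topk_below_one_rejected(self, small_dataset):
        with pytest.raises(ValidationError, match="top_k"):
            rank_unknown(small_dataset, top_k=0)
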