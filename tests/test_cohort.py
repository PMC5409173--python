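"""Cohort statistics: Mann–Whitney, ROC/AUC with DeLong CIs, paired AUC
comparison, lesion summarisation and the full analysis table."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from frocdwi.cohort import (
    BENIGN,
    MALIGNANT,
    LesionRecord,
    compare_aucs,
    group_compare,
    roc_auc,
    run_cohort_analysis,
    summarize_lesion,
)
from frocdwi.errors import AnalysisError
from frocdwi.fitting import ParameterMaps


def brute_force_auc(pos, neg):
    """All-pairs concordance with ties counting 1/2."""
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def labels_for(n_pos, n_neg):
    return np.array([MALIGNANT] * n_pos + [BENIGN] * n_neg)


class TestGroupCompare:
    def test_identical_groups_symmetric(self):
        vals = np.r_[[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]]
        gc = group_compare(vals, labels_for(4, 4))
        assert gc.U == 8.0  # n1*n2/2
        assert gc.p > 0.9

    def test_separated_groups_exact_enumeration(self):
        """{1,2,3} vs {4,5,6}: U = 0, exact two-sided p = 0.1 — verified
        against full enumeration of all 20 label assignments."""
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        labels = np.array([MALIGNANT] * 3 + [BENIGN] * 3)
        gc = group_compare(vals, labels)
        assert gc.U == 0.0
        assert gc.method == "exact"

        # exhaustive permutation oracle
        u_obs = 0.0
        u_all = []
        for pos_idx in itertools.combinations(range(6), 3):
            pos = vals[list(pos_idx)]
            neg = np.delete(vals, list(pos_idx))
            u = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            u_all.append(u)
        u_all = np.array(u_all)
        # two-sided: as-or-more-extreme in either tail
        p_exact = np.mean(np.minimum(u_all, 9 - u_all) <= min(u_obs, 9 - u_obs))
        assert p_exact == pytest.approx(0.1)
        assert gc.p == pytest.approx(0.1)

    def test_quartiles_reproduce_constructed_group(self):
        """A group built to have specific quartiles reports exactly the
        printed malignant D_app quartiles 0.87 / 0.97 / 1.01."""
        malignant = np.array([0.80, 0.87, 0.97, 1.01, 1.30])
        benign = np.array([1.0, 1.2, 1.4])
        vals = np.r_[malignant, benign]
        gc = group_compare(vals, labels_for(5, 3))
        assert gc.q25_malignant == pytest.approx(0.87)
        assert gc.median_malignant == pytest.approx(0.97)
        assert gc.q75_malignant == pytest.approx(1.01)

    def test_ties_switch_to_asymptotic(self):
        vals = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        gc = group_compare(vals, labels_for(3, 3))
        assert gc.method == "asymptotic"

    def test_large_samples_use_asymptotic(self, rng):
        vals = rng.normal(size=60)
        gc = group_compare(vals, labels_for(30, 30))
        assert gc.method == "asymptotic"

    def test_empty_group_rejected(self):
        with pytest.raises(AnalysisError):
            group_compare([1.0, 2.0], np.array([MALIGNANT, MALIGNANT]))


class TestROCAUC:
    def test_perfect_separation(self):
        vals = np.array([10.0, 9.0, 8.0, 1.0, 2.0])
        roc = roc_auc(vals, labels_for(3, 2))
        assert roc.auc == 1.0
        assert roc.ci_low <= roc.auc <= roc.ci_high <= 1.0

    def test_auc_u_identity_with_ties(self, rng):
        """AUC equals the brute-force pairwise concordance ratio on
        random (tied) instances."""
        for _ in range(200):
            n1 = rng.integers(2, 12)
            n2 = rng.integers(2, 12)
            vals = rng.integers(0, 6, n1 + n2).astype(float)  # heavy ties
            labels = labels_for(n1, n2)
            roc = roc_auc(vals, labels, orientation="higher")
            expected = brute_force_auc(vals[:n1], vals[n1:])
            assert roc.auc == pytest.approx(expected, abs=1e-12)

    def test_auto_orientation_lower_scores_malignancy(self, rng):
        # diffusivity-like: malignant values lower
        vals = np.r_[rng.normal(0.9, 0.1, 20), rng.normal(1.3, 0.1, 15)]
        roc = roc_auc(vals, labels_for(20, 15))
        assert roc.orientation == "lower"
        assert roc.auc >= 0.5

    def test_label_flip_antisymmetry(self, rng):
        vals = rng.normal(size=30)
        labels = labels_for(14, 16)
        flipped = np.where(labels == MALIGNANT, BENIGN, MALIGNANT)
        a = roc_auc(vals, labels, orientation="higher").auc
        b = roc_auc(vals, flipped, orientation="higher").auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_random_labels_near_chance(self, rng):
        vals = rng.normal(size=2000)
        roc = roc_auc(vals, labels_for(1000, 1000), orientation="higher")
        assert abs(roc.auc - 0.5) < 0.05

    def test_one_class_rejected(self):
        with pytest.raises(AnalysisError):
            roc_auc([1.0, 2.0], np.array([MALIGNANT, MALIGNANT]))

    def test_delong_ci_against_known_case(self, rng):
        """DeLong variance sanity: CI width shrinks ~ 1/sqrt(n) and the
        CI covers the population AUC in a well-powered case."""
        pop_auc = stats.norm.cdf(1.0 / np.sqrt(2))  # two unit normals 1 apart
        small = roc_auc(
            np.r_[rng.normal(1, 1, 30), rng.normal(0, 1, 30)],
            labels_for(30, 30),
            orientation="higher",
        )
        big = roc_auc(
            np.r_[rng.normal(1, 1, 3000), rng.normal(0, 1, 3000)],
            labels_for(3000, 3000),
            orientation="higher",
        )
        assert (big.ci_high - big.ci_low) < (small.ci_high - small.ci_low)
        assert big.ci_low < pop_auc < big.ci_high


class TestCompareAUCs:
    def test_identical_scores_null(self, rng):
        vals = rng.normal(size=20)
        labels = labels_for(10, 10)
        cmp_ = compare_aucs(vals, vals.copy(), labels)
        assert cmp_.area_difference == 0.0
        assert cmp_.p == 1.0

    def test_difference_matches_componentwise_oracle(self, rng):
        """area_difference equals the independently computed AUC
        difference, including for anti-correlated scores (auto-oriented
        before comparison)."""
        labels = labels_for(12, 10)
        informative = np.r_[rng.normal(2, 1, 12), rng.normal(0, 1, 10)]
        anti = -informative  # perfectly anti-correlated
        cmp_ = compare_aucs(informative, anti, labels)
        auc_a = roc_auc(informative, labels).auc
        auc_b = roc_auc(anti, labels).auc
        assert cmp_.area_difference == pytest.approx(auc_a - auc_b, abs=1e-12)
        assert cmp_.area_difference == 0.0  # orientation makes them equal

    def test_delong_p_matches_paired_bootstrap_oracle(self, rng):
        """On a small paired case the DeLong p agrees with a
        100k-resample stratified-bootstrap z-test within 0.02."""
        n = 8
        base = rng.normal(0, 1, 2 * n)
        labels = labels_for(n, n)
        score_a = base + np.r_[np.full(n, 1.2), np.zeros(n)]
        score_b = 0.7 * base + rng.normal(0, 0.8, 2 * n) + np.r_[
            np.full(n, 0.4), np.zeros(n)
        ]
        cmp_ = compare_aucs(score_a, score_b, labels)

        # orient as compare_aucs does
        sa = score_a if roc_auc(score_a, labels).orientation == "higher" else -score_a
        sb = score_b if roc_auc(score_b, labels).orientation == "higher" else -score_b
        pa, na = sa[:n], sa[n:]
        pb, nb = sb[:n], sb[n:]

        def vec_auc(pos, neg):
            # pos, neg: (B, n) resampled scores
            return np.mean(
                (pos[:, :, None] > neg[:, None, :])
                + 0.5 * (pos[:, :, None] == neg[:, None, :]),
                axis=(1, 2),
            )

        B = 100_000
        boot_rng = np.random.default_rng(7)
        ip = boot_rng.integers(0, n, (B, n))
        ineg = boot_rng.integers(0, n, (B, n))
        diffs = vec_auc(pa[ip], na[ineg]) - vec_auc(pb[ip], nb[ineg])
        obs = brute_force_auc(pa, na) - brute_force_auc(pb, nb)
        p_boot = 2 * stats.norm.sf(abs(obs) / diffs.std(ddof=1))
        assert cmp_.p == pytest.approx(p_boot, abs=0.02)

    def test_bootstrap_method_available(self, rng):
        labels = labels_for(6, 6)
        a = np.r_[rng.normal(1, 1, 6), rng.normal(0, 1, 6)]
        b = np.r_[rng.normal(0.5, 1, 6), rng.normal(0, 1, 6)]
        cmp_ = compare_aucs(a, b, labels, method="bootstrap", n_boot=500, seed=3)
        assert 0 <= cmp_.p <= 1

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(AnalysisError):
            compare_aucs([1.0, 2.0], [1.0], np.array([MALIGNANT, BENIGN]))


@settings(max_examples=80, deadline=None, derandomize=True)
@given(
    data=st.lists(
        st.tuples(st.integers(0, 8), st.booleans()), min_size=4, max_size=20
    )
)
def test_auc_monotone_transform_invariance(data):
    """AUC and U are invariant under strictly increasing transforms and
    AUC always equals the pairwise concordance ratio."""
    vals = np.array([float(v) for v, _ in data])
    labels = np.array([MALIGNANT if m else BENIGN for _, m in data])
    n1 = int((labels == MALIGNANT).sum())
    n2 = len(labels) - n1
    if n1 == 0 or n2 == 0:
        return
    roc1 = roc_auc(vals, labels, orientation="higher")
    transformed = np.exp(vals) + 3 * vals  # strictly increasing
    roc2 = roc_auc(transformed, labels, orientation="higher")
    assert roc1.auc == pytest.approx(roc2.auc, abs=1e-12)
    expected = brute_force_auc(vals[labels == MALIGNANT], vals[labels == BENIGN])
    assert roc1.auc == pytest.approx(expected, abs=1e-12)


class TestSummarizeLesion:
    def _maps(self, arr, valid=None):
        valid = np.ones(arr.shape, dtype=bool) if valid is None else valid
        return ParameterMaps(
            model="mono", maps={"d_app": arr.astype(float)}, valid=valid
        )

    def test_single_voxel_roi(self):
        arr = np.arange(8.0).reshape(2, 2, 2)
        roi = np.zeros((2, 2, 2), dtype=int)
        roi[1, 0, 1] = 3
        out = summarize_lesion(self._maps(arr), roi, 3)
        assert out["d_app"] == arr[1, 0, 1]

    def test_uniform_value(self):
        arr = np.full((3, 3, 1), 1.7)
        roi = np.ones((3, 3, 1), dtype=int)
        assert summarize_lesion(self._maps(arr), roi, 1)["d_app"] == 1.7

    def test_mean_matches_brute_force(self, rng):
        arr = rng.random((5, 5, 4))
        roi = np.zeros((5, 5, 4), dtype=int)
        sel = rng.random((5, 5, 4)) < 0.5
        roi[sel] = 2
        out = summarize_lesion(self._maps(arr), roi, 2)
        total, count = 0.0, 0
        for idx in np.ndindex(arr.shape):
            if roi[idx] == 2:
                total += arr[idx]
                count += 1
        assert out["d_app"] == pytest.approx(total / count, abs=1e-12)

    def test_invalid_voxels_excluded(self):
        arr = np.array([[[1.0, 5.0]]])
        valid = np.array([[[True, False]]])
        roi = np.ones((1, 1, 2), dtype=int)
        out = summarize_lesion(self._maps(arr, valid), roi, 1)
        assert out["d_app"] == 1.0

    def test_empty_roi_error_names_lesion(self):
        arr = np.ones((2, 2, 2))
        with pytest.raises(AnalysisError, match="lesion 9"):
            summarize_lesion(self._maps(arr), np.zeros((2, 2, 2), dtype=int), 9)


def _toy_records(rng, n_mal=10, n_ben=8, d_gap=0.4):
    records = []
    for i in range(n_mal + n_ben):
        malignant = i < n_mal
        d = rng.normal(1.0 if malignant else 1.0 + d_gap, 0.1)
        records.append(
            LesionRecord(
                lesion_id=i + 1,
                label=MALIGNANT if malignant else BENIGN,
                size_mm=float(rng.uniform(5, 20)),
                summaries={"d_app": d, "beta_froc": rng.normal(0.7, 0.05)},
            )
        )
    return records


class TestRunCohortAnalysis:
    def test_perfectly_separated_cohort_all_aucs_one(self, rng):
        records = []
        for i in range(10):
            malignant = i < 5
            records.append(
                LesionRecord(
                    lesion_id=i + 1,
                    label=MALIGNANT if malignant else BENIGN,
                    size_mm=12.0,
                    summaries={"d_app": 0.9 + 0.01 * i if malignant else 1.5 + 0.01 * i},
                )
            )
        ana = run_cohort_analysis(records)
        assert ana.rocs["all"]["d_app"].auc == 1.0

    def test_table_structure(self, rng):
        ana = run_cohort_analysis(_toy_records(rng))
        df = ana.to_frame()
        assert set(df["subgroup"]) <= {"all", "le_threshold", "gt_threshold"}
        sub = df[df.subgroup == "all"]
        assert list(sub["parameter"]) == ["beta_froc", "d_app"]
        assert np.isnan(
            sub.loc[sub.parameter == "d_app", "p_vs_ref"].iloc[0]
        )  # no self-comparison for the reference
        assert np.isfinite(
            sub.loc[sub.parameter == "beta_froc", "p_vs_ref"].iloc[0]
        )

    def test_degenerate_threshold_split(self, rng):
        records = _toy_records(rng)
        ana = run_cohort_analysis(records, size_threshold_mm=100.0)
        # no lesion exceeds 100 mm: large subgroup flagged, small == all
        assert "gt_threshold" in ana.not_computable
        assert (
            ana.comparisons["le_threshold"]["d_app"].U
            == ana.comparisons["all"]["d_app"].U
        )

    def test_too_few_lesions_rejected(self, rng):
        records = _toy_records(rng)[:3]
        with pytest.raises(AnalysisError):
            run_cohort_analysis(records)
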