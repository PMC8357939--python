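"""Dice, STAPLE consensus and discipline comparison tests.

The STAPLE implementation is checked against an independently coded
brute-force EM (explicit per-voxel loops over the same model) and against
SimpleITK's STAPLE filter on a well-separated example.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from segrobust import (
    BinaryMask,
    compare_disciplines_dsc,
    compare_volumes,
    dice,
    grade_agreement,
    per_patient_agreement,
    staple,
)

from conftest import ball_mask, mask_from


# ---------------------------------------------------------------------------
# Independent brute-force EM oracle (same model: scalar prior = mean
# foreground fraction, p = q = 0.99999 at start, binarize at 0.5)
# ---------------------------------------------------------------------------

def brute_force_staple(decisions: np.ndarray, tol=1e-6, max_iter=100):
    """Plain-python EM over (voxels x observers) binary decisions."""
    n_vox, n_obs = decisions.shape
    prior = decisions.mean()
    p = [0.99999] * n_obs
    q = [0.99999] * n_obs
    w = [prior] * n_vox
    for _ in range(max_iter):
        for i in range(n_vox):
            a = prior
            b = 1.0 - prior
            for j in range(n_obs):
                if decisions[i, j]:
                    a *= p[j]
                    b *= 1.0 - q[j]
                else:
                    a *= 1.0 - p[j]
                    b *= q[j]
            w[i] = a / (a + b) if (a + b) > 0 else prior
        delta = 0.0
        for j in range(n_obs):
            sw = sum(w)
            swc = sum(1.0 - wi for wi in w)
            pj = sum(w[i] for i in range(n_vox) if decisions[i, j]) / sw
            qj = sum(1.0 - w[i] for i in range(n_vox) if not decisions[i, j]) / swc
            pj = min(max(pj, 1e-8), 1 - 1e-8)
            qj = min(max(qj, 1e-8), 1 - 1e-8)
            delta = max(delta, abs(pj - p[j]), abs(qj - q[j]))
            p[j], q[j] = pj, qj
        if delta < tol:
            break
    return np.array(w), np.array(p), np.array(q)


def _masks_from_decisions(decisions, shape):
    """Embed flat per-observer decisions into small full-grid masks."""
    masks = []
    for j in range(decisions.shape[1]):
        arr = np.zeros(np.prod(shape), bool)
        arr[: decisions.shape[0]] = decisions[:, j]
        masks.append(mask_from(arr.reshape(shape)))
    return masks


class TestDice:
    def test_identity(self):
        m = ball_mask((10, 10, 10), (5, 5, 5), 3.0)
        assert dice(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        assert dice(mask_from(a), mask_from(b)) == 0.0

    def test_half_overlap(self):
        # |A| = |B| = 4, |A ∩ B| = 2 -> 2*2/(4+4) = 0.5
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a.ravel()[[0, 1, 2, 3]] = True
        b.ravel()[[2, 3, 4, 5]] = True
        assert dice(mask_from(a), mask_from(b)) == 0.5

    def test_both_empty_convention(self):
        z = mask_from(np.zeros((3, 3, 3), bool))
        assert dice(z, z) == 1.0

    def test_geometry_mismatch(self):
        a = mask_from(np.ones((3, 3, 3), bool))
        b = BinaryMask(np.ones((3, 3, 3), bool), (2.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            dice(a, b)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**12 - 1), st.integers(0, 2**12 - 1))
    def test_symmetric_and_bounded(self, bits_a, bits_b):
        a = mask_from(np.array([(bits_a >> i) & 1 for i in range(12)], bool).reshape(3, 2, 2))
        b = mask_from(np.array([(bits_b >> i) & 1 for i in range(12)], bool).reshape(3, 2, 2))
        d1 = dice(a, b)
        assert d1 == dice(b, a)
        assert 0.0 <= d1 <= 1.0
        if bits_a == bits_b and bits_a != 0:
            assert d1 == 1.0


class TestStaple:
    def test_unanimous_observers(self):
        m = ball_mask((12, 12, 12), (6, 6, 6), 4.0)
        res = staple([m, m, m])
        np.testing.assert_array_equal(res.consensus.indicator, m.indicator)
        assert np.all(res.sensitivity > 1 - 1e-4)
        assert np.all(res.specificity > 1 - 1e-4)
        assert res.converged

    def test_majority_five_of_six(self):
        """Symmetric observers: a 5-of-6 voxel enters the consensus, a
        1-of-6 voxel does not (equivalent to majority vote)."""
        rng = np.random.default_rng(5)
        base = rng.random(64) < 0.4
        decisions = np.tile(base[:, None], (1, 6))
        # voxel 0: marked by 5 of 6; voxel 1: marked by 1 of 6
        decisions[0, :] = [1, 1, 1, 1, 1, 0]
        decisions[1, :] = [1, 0, 0, 0, 0, 0]
        masks = _masks_from_decisions(decisions, (4, 4, 4))
        res = staple(masks)
        assert res.consensus.indicator.ravel()[0]
        assert not res.consensus.indicator.ravel()[1]
        # cross-check full posterior with the brute-force EM
        w, p, q = brute_force_staple(decisions)
        np.testing.assert_allclose(
            res.probability_map.ravel()[:64], w, atol=1e-8
        )

    def test_matches_brute_force_em_random(self):
        """EM equivalence on random ≤200-voxel problems, ≤4 observers."""
        rng = np.random.default_rng(11)
        for trial in range(8):
            n_obs = int(rng.integers(2, 5))
            shape = (5, 5, 5)
            truth = rng.random(125) < 0.3
            decisions = np.zeros((125, n_obs), bool)
            for j in range(n_obs):
                flip = rng.random(125) < 0.1
                decisions[:, j] = truth ^ flip
            if not decisions.any() or decisions.all():
                continue
            masks = _masks_from_decisions(decisions, shape)
            res = staple(masks)
            w, p, q = brute_force_staple(decisions)
            np.testing.assert_allclose(res.probability_map.ravel(), w, atol=1e-8)
            np.testing.assert_allclose(res.sensitivity, p, atol=1e-8)
            np.testing.assert_allclose(res.specificity, q, atol=1e-8)

    def test_complementary_masks_give_no_signal(self):
        """Two observers with complementary equal-size masks: the posterior
        stays at the prior everywhere (no consensus signal)."""
        a = np.zeros(10, bool)
        a[:5] = True
        decisions = np.stack([a, ~a], axis=1)
        masks = _masks_from_decisions(decisions, (10, 1, 1))
        res = staple(masks)
        w, _, _ = brute_force_staple(decisions)
        np.testing.assert_allclose(res.probability_map.ravel(), w, atol=1e-8)
        np.testing.assert_allclose(res.probability_map.ravel(), 0.5, atol=1e-3)

    def test_observer_order_invariance(self):
        rng = np.random.default_rng(3)
        masks = [
            ball_mask((14, 14, 14), (7 + rng.integers(-1, 2), 7, 7), 4.0 + rng.random())
            for _ in range(4)
        ]
        res1 = staple(masks)
        res2 = staple(masks[::-1])
        np.testing.assert_allclose(res1.probability_map, res2.probability_map, atol=1e-9)
        np.testing.assert_allclose(res1.sensitivity, res2.sensitivity[::-1], atol=1e-9)

    def test_matches_simpleitk_consensus(self):
        """Binarized consensus agrees with SimpleITK's STAPLE filter."""
        sitk = pytest.importorskip("SimpleITK")
        rng = np.random.default_rng(17)
        masks = []
        for _ in range(4):
            m = ball_mask(
                (20, 20, 20),
                (10 + rng.integers(-2, 3), 10 + rng.integers(-2, 3), 10),
                6.0 + rng.random() * 2,
            )
            masks.append(m)
        res = staple(masks)
        imgs = [
            sitk.GetImageFromArray(m.indicator.astype(np.uint8).transpose(2, 1, 0))
            for m in masks
        ]
        prob = sitk.GetArrayFromImage(sitk.STAPLE(imgs, 1.0)).transpose(2, 1, 0)
        np.testing.assert_array_equal(res.consensus.indicator, prob >= 0.5)

    def test_all_empty_rejected(self):
        z = mask_from(np.zeros((3, 3, 3), bool))
        with pytest.raises(ValueError, match="empty"):
            staple([z, z])

    def test_fewer_than_two_masks_rejected(self):
        m = ball_mask((6, 6, 6), (3, 3, 3), 2.0)
        with pytest.raises(ValueError):
            staple([m])


class TestGrading:
    @pytest.mark.parametrize(
        "dsc,grade",
        [
            (0.85, "High"),
            (0.9, "High"),
            (0.8499, "Medium"),
            (0.70, "Medium"),
            (0.6999, "Low"),
            (0.5, "Low"),
            (0.49, "VeryLow"),
            (0.0, "VeryLow"),
            (1.0, "High"),
        ],
    )
    def test_boundaries(self, dsc, grade):
        assert grade_agreement(dsc) == grade

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            grade_agreement(1.2)

    def test_partition_no_gaps(self):
        for d in np.linspace(0, 1, 2001):
            assert grade_agreement(float(d)) in ("High", "Medium", "Low", "VeryLow")


class TestAgreementRecords:
    def test_identical_observers_all_dsc_one(self):
        from dataclasses import replace

        from segrobust import ObserverProfile, generate_cohort

        from conftest import small_cohort_config

        observers = tuple(
            ObserverProfile(f"{d}{i}", d, 1.0, 0.0) for d in "AB" for i in range(2)
        )
        cfg = replace(small_cohort_config(n_patients=3), observers=observers)
        cohort = generate_cohort(cfg)
        records, summary, _ = per_patient_agreement(cohort)
        assert np.allclose(records["dsc"], 1.0)
        assert np.allclose(summary["sd"].fillna(0.0), 0.0)
        assert set(records["grade"]) == {"High"}

    def test_records_match_direct_dice(self, small_cohort):
        records, _, results = per_patient_agreement(small_cohort)
        case = small_cohort.patients[0]
        consensus = results[case.patient_id].consensus
        for obs, mask in case.observer_masks.items():
            row = records[
                (records["patient_id"] == case.patient_id)
                & (records["observer_id"] == obs)
            ]
            assert row["dsc"].iloc[0] == pytest.approx(dice(mask, consensus))

    def test_discipline_direction(self, small_cohort):
        records, _, _ = per_patient_agreement(small_cohort)
        cmp = compare_disciplines_dsc(records)
        assert cmp["mean_dsc_a"] > cmp["mean_dsc_b"]


class TestDisciplineComparisons:
    def test_identical_means_give_null(self):
        import pandas as pd

        rows = []
        for p in range(4):
            rows.append(dict(patient_id=p, discipline="A", dsc=0.8, observer_id="A1"))
            rows.append(dict(patient_id=p, discipline="B", dsc=0.8, observer_id="B1"))
        cmp = compare_disciplines_dsc(pd.DataFrame(rows))
        assert cmp["t_statistic"] == 0.0
        assert cmp["p_value"] == 1.0

    def test_hand_computed_paired_t(self):
        import pandas as pd

        pairs = [(0.8, 0.6), (0.9, 0.7), (0.85, 0.66)]
        rows = []
        for p, (a, b) in enumerate(pairs):
            rows.append(dict(patient_id=p, discipline="A", dsc=a, observer_id="A1"))
            rows.append(dict(patient_id=p, discipline="B", dsc=b, observer_id="B1"))
        cmp = compare_disciplines_dsc(pd.DataFrame(rows))
        diffs = np.array([a - b for a, b in pairs])
        t_expect = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(len(diffs)))
        p_expect = 2 * stats.t.sf(abs(t_expect), df=len(diffs) - 1)
        assert cmp["t_statistic"] == pytest.approx(t_expect)
        assert cmp["p_value"] == pytest.approx(p_expect)

    def test_constant_offset_degenerate(self):
        import pandas as pd

        rows = []
        for p in range(3):
            rows.append(dict(patient_id=p, discipline="A", dsc=0.8, observer_id="A1"))
            rows.append(dict(patient_id=p, discipline="B", dsc=0.6, observer_id="B1"))
        cmp = compare_disciplines_dsc(pd.DataFrame(rows))
        assert cmp["p_value"] == 0.0

    def test_volume_arithmetic_and_direction(self, small_cohort):
        cmp = compare_volumes(small_cohort)
        assert cmp["mean_volume_b_cm3"] < cmp["mean_volume_a_cm3"]
        # bias 0.66 should put the ratio in a loose band
        ratio = cmp["mean_volume_b_cm3"] / cmp["mean_volume_a_cm3"]
        assert 0.5 < ratio < 0.8

    def test_unbiased_cohort_is_null(self):
        """Same profiles in both disciplines: volume comparison not significant."""
        from conftest import small_cohort_config
        from segrobust import generate_cohort

        cfg = small_cohort_config(n_patients=8, noise_a=3.0, noise_b=3.0, bias_b=1.0)
        cohort = generate_cohort(cfg)
        cmp = compare_volumes(cohort)
        assert cmp["p_value"] > 0.01
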