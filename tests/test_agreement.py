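import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from irtkit import (
    ROIMask,
    bland_altman_rm,
    dice,
    dice_bin,
    method_comparison,
    summarize_dice,
)
from irtkit.registration import DeformationModel
from irtkit.errors import InputError, UndefinedDiceError


def _mask(arr):
    return ROIMask(np.asarray(arr, dtype=np.uint8))


def _square(shape, y0, x0, side):
    m = np.zeros(shape, dtype=np.uint8)
    m[y0 : y0 + side, x0 : x0 + side] = 1
    return ROIMask(m)


class TestDice:
    def test_identical_masks(self):
        m = _square((8, 8), 2, 2, 3)
        r = dice(m, m)
        assert (r.value, r.bin) == (1.0, "excellent")

    def test_disjoint_masks(self):
        a = _square((8, 8), 0, 0, 2)
        b = _square((8, 8), 5, 5, 2)
        r = dice(a, b)
        assert (r.value, r.bin) == (0.0, "poor")

    def test_shifted_square_hand_count(self):
        # 2x2 squares, shifted one column: |A| = |B| = 4, overlap 2
        a = _square((6, 6), 2, 2, 2)
        b = _square((6, 6), 2, 3, 2)
        r = dice(a, b)
        assert r.value == 0.5
        assert r.bin == "moderate"

    def test_both_empty_undefined(self):
        z = _mask(np.zeros((4, 4)))
        with pytest.raises(UndefinedDiceError):
            dice(z, z)

    def test_one_empty_is_zero(self):
        a = _square((6, 6), 1, 1, 2)
        z = _mask(np.zeros((6, 6)))
        assert dice(a, z).value == 0.0

    @hsettings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = _mask(rng.integers(0, 2, size=(10, 10)))
        b = _mask(rng.integers(0, 2, size=(10, 10)))
        if a.values.sum() + b.values.sum() == 0:
            return
        assert dice(a, b).value == dice(b, a).value

    def test_monotone_in_overlap(self):
        # grow overlap with |A|, |B| fixed
        a = _square((8, 8), 2, 2, 3)
        prev = 0.0
        for shift in (3, 2, 1, 0):
            b = _square((8, 8), 2, 2 + shift, 3)
            val = dice(a, b).value
            assert val >= prev
            prev = val

    def test_bin_edges(self):
        expected = {
            0.49: "poor",
            0.5: "moderate",
            0.69: "moderate",
            0.7: "good",
            0.89: "good",
            0.9: "excellent",
        }
        for v, label in expected.items():
            assert dice_bin(v) == label
        assert dice_bin(0.895) == "good"  # no rounding before binning


class TestBlandAltmanRM:
    def test_constant_differences(self):
        res = bland_altman_rm([[0.1] * 4, [0.1] * 4, [0.1] * 4])
        assert res.bias == pytest.approx(0.1)
        assert res.loa_lower == pytest.approx(0.1)
        assert res.loa_upper == pytest.approx(0.1)
        assert res.sd_total == pytest.approx(0.0, abs=1e-12)

    def test_single_obs_closed_form(self):
        res = bland_altman_rm([[-1.0], [0.0], [1.0]])
        assert res.bias == 0.0
        assert res.sd_total == pytest.approx(1.0)
        assert res.loa_upper == pytest.approx(1.96)
        assert res.loa_lower == pytest.approx(-1.96)

    @hsettings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.integers(3, 20))
    def test_single_obs_reduces_to_classical(self, seed, n):
        rng = np.random.default_rng(seed)
        d = rng.normal(0.2, 0.5, size=n)
        res = bland_altman_rm([[x] for x in d])
        assert res.bias == pytest.approx(d.mean())
        assert res.sd_total == pytest.approx(d.std(ddof=1))

    def test_variance_component_recovery(self):
        rng = np.random.default_rng(99)
        sigma_b, sigma_w = 0.3, 0.2
        subjects = rng.normal(0, sigma_b, size=200)
        diffs = [
            (0.1 + s + rng.normal(0, sigma_w, size=4)).tolist()
            for s in subjects
        ]
        res = bland_altman_rm(diffs)
        target = np.sqrt(sigma_b**2 + sigma_w**2)
        assert abs(res.sd_total - target) / target < 0.10
        assert res.n_subjects == 200
        assert res.n_obs == 800

    def test_loa_bracket_bias(self):
        rng = np.random.default_rng(5)
        diffs = [rng.normal(0.3, 0.4, size=3).tolist() for _ in range(10)]
        res = bland_altman_rm(diffs)
        assert res.loa_lower <= res.bias <= res.loa_upper
        assert res.loa_upper - res.bias == pytest.approx(1.96 * res.sd_total)

    def test_input_validation(self):
        with pytest.raises(InputError):
            bland_altman_rm([[1.0]])
        with pytest.raises(InputError):
            bland_altman_rm([[1.0], []])


class TestMethodComparison:
    def test_identity_models(self):
        ref = _square((20, 20), 5, 5, 6)
        models = [DeformationModel.identity((20, 20), 4) for _ in range(3)]
        results = method_comparison(ref, [ref, ref, ref], models)
        assert all(r.value == 1.0 for r in results)

    def test_known_field_inverted(self):
        # follow-up mask is the reference shifted by +2 columns; a model
        # sampling from x+2 maps it back exactly
        ref = _square((20, 20), 5, 5, 6)
        moved = _square((20, 20), 5, 7, 6)
        model = DeformationModel.identity((20, 20), 4)
        model.coeff[..., 0] = 2.0
        (r,) = method_comparison(ref, [moved], [model])
        assert r.value == 1.0

    def test_count_mismatch(self):
        ref = _square((10, 10), 2, 2, 3)
        with pytest.raises(InputError):
            method_comparison(ref, [ref], [])

    def test_summary_formatting(self):
        ref = _square((20, 20), 5, 5, 6)
        near = _square((20, 20), 5, 6, 6)
        models = [DeformationModel.identity((20, 20), 4) for _ in range(2)]
        results = method_comparison(ref, [ref, near], models)
        summary = summarize_dice(results)
        assert summary["min"] <= summary["mean"] <= summary["max"]
        assert summary["formatted"].startswith("Dice = ")
        assert "range: [" in summary["formatted"]
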