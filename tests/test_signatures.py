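"""Unit tests for the signature data model and preprocessing rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import qfasa as q
from conftest import make_matrix


def _positive_rows(k=5, n=2):
    return st.lists(
        st.lists(
            st.floats(1e-3, 1.0, allow_nan=False), min_size=k, max_size=k
        ),
        min_size=n, max_size=n,
    )


class TestSignatureMatrix:
    def test_rejects_negative_values(self):
        with pytest.raises(ValueError, match="negative"):
            make_matrix([[0.5, -0.1, 0.6]])

    def test_completed_flag_checks_row_sums(self):
        with pytest.raises(ValueError, match="sums to"):
            make_matrix([[0.5, 0.4]], completed=True)
        make_matrix([[0.5, 0.5]], completed=True)  # fine

    def test_duplicate_fa_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            make_matrix([[0.5, 0.5]], fa_names=["a", "a"])


class TestLoadSignatures:
    def _write(self, tmp_path, rows, cols=("fa_a", "fa_b", "fa_c")):
        df = pd.DataFrame(rows, columns=list(cols))
        df.insert(0, "id", [f"r{i}" for i in range(len(df))])
        path = tmp_path / "sig.csv"
        df.to_csv(path, index=False)
        return path

    def test_proportion_file_read_unchanged(self, tmp_path):
        rows = [[0.2, 0.3, 0.5], [0.1, 0.1, 0.8], [0.4, 0.4, 0.2]]
        sig, labels = q.load_signatures(self._write(tmp_path, rows))
        assert sig.n == 3 and sig.completed
        np.testing.assert_array_equal(sig.proportions, rows)

    def test_percent_dialect_divided_by_100(self, tmp_path):
        rows = [[20.0, 30.0, 50.0], [10.0, 10.0, 80.0]]
        sig, _ = q.load_signatures(self._write(tmp_path, rows))
        np.testing.assert_allclose(sig.proportions.sum(axis=1), 1.0)
        np.testing.assert_allclose(sig.proportions[0], [0.2, 0.3, 0.5])

    def test_negative_cell_names_row_and_column(self, tmp_path):
        path = self._write(tmp_path, [[0.2, -0.3, 0.5]])
        with pytest.raises(ValueError, match=r"r0.*fa_b"):
            q.load_signatures(path)

    def test_ambiguous_dialect_rejected(self, tmp_path):
        path = self._write(tmp_path, [[0.2, 0.3, 0.5], [20.0, 30.0, 50.0]])
        with pytest.raises(ValueError, match="ambiguous"):
            q.load_signatures(path)

    def test_labels_split_off(self, tmp_path):
        df = pd.DataFrame(
            {"id": ["a"], "group": ["g1"], "fa_a": [0.4], "fa_b": [0.6]}
        )
        path = tmp_path / "sig.csv"
        df.to_csv(path, index=False)
        sig, labels = q.load_signatures(path)
        assert sig.fa_names == ["fa_a", "fa_b"]
        assert labels["group"].tolist() == ["g1"]


class TestReplaceZeros:
    def test_zero_free_rows_bit_identical(self):
        data = make_matrix([[0.25, 0.25, 0.5]])
        ref = make_matrix([[0.004, 0.5, 0.496]])
        out = q.replace_zeros(data, ref)
        assert out.proportions[0].tobytes() == data.proportions[0].tobytes()

    def test_floor_and_rescale(self):
        # floor = 0.9 * 0.004 = 0.0036; row rescaled by 1/1.0036
        ref = make_matrix([[0.004, 0.5, 0.496]])
        data = make_matrix([[0.0, 0.6, 0.4]])
        out = q.replace_zeros(data, ref)
        np.testing.assert_allclose(
            out.proportions[0],
            [0.0036 / 1.0036, 0.6 / 1.0036, 0.4 / 1.0036],
            rtol=1e-12,
        )
        assert abs(out.proportions[0].sum() - 1.0) < 1e-12
        # multiplicative rescale preserves the nonzero entries' ratio
        assert out.proportions[0, 1] / out.proportions[0, 2] == (
            pytest.approx(1.5, abs=1e-12)
        )

    def test_floor_from_all_reference_cells(self):
        # smallest non-zero anywhere in the reference, not per column
        ref = make_matrix([[0.01, 0.99, 0.0], [0.5, 0.3, 0.2]])
        data = make_matrix([[0.0, 0.5, 0.5]])
        out = q.replace_zeros(data, ref)
        assert np.isclose(out.proportions[0, 0], 0.009 / 1.009)

    def test_all_zero_row_fails(self):
        ref = make_matrix([[0.004, 0.996]])
        with pytest.raises(ValueError, match="entirely zero"):
            q.replace_zeros(make_matrix([[0.0, 0.0]]), ref)


class TestNormalizeAndAugment:
    def test_normalize_rescales_subset(self):
        data = make_matrix([[0.2, 0.2, 0.6]], fa_names=["a", "b", "c"])
        out = q.normalize_multiplicative(data, ["a", "b"])
        np.testing.assert_allclose(out.proportions[0], [0.5, 0.5])
        assert out.completed

    def test_normalize_identity_when_subset_complete(self):
        data = make_matrix([[0.3, 0.7]], fa_names=["a", "b"])
        out = q.normalize_multiplicative(data, ["a", "b"])
        np.testing.assert_array_equal(out.proportions, data.proportions)

    def test_normalize_zero_subset_sum_names_row(self):
        data = make_matrix([[0.0, 0.0, 1.0]], fa_names=["a", "b", "c"],
                           ids=["bear7"])
        with pytest.raises(ValueError, match="bear7"):
            q.normalize_multiplicative(data, ["a", "b"])

    def test_augment_complement(self):
        data = make_matrix([[0.53, 0.4, 0.07]], fa_names=["a", "b", "c"],
                           completed=True)
        out = q.augment(data, ["a", "b"])
        assert out.fa_names == ["a", "b", q.AUGMENTED_NAME]
        np.testing.assert_allclose(out.proportions[0], [0.53, 0.4, 0.07])

    def test_augment_full_subset_gives_zero_component(self):
        data = make_matrix([[0.6, 0.4]], fa_names=["a", "b"], completed=True)
        out = q.augment(data, ["a", "b"])
        assert out.proportions[0, -1] == 0.0

    @given(_positive_rows(k=6, n=3))
    @settings(max_examples=25, deadline=None)
    def test_augment_preserves_ratios_normalize_preserves_subset_ratios(
        self, raw
    ):
        raw = np.asarray(raw)
        raw = raw / raw.sum(axis=1, keepdims=True)
        data = make_matrix(raw, completed=True)
        subset = data.fa_names[:4]
        aug = q.augment(data, subset)
        norm = q.normalize_multiplicative(data, subset)
        ratio = raw[:, 0] / raw[:, 1]
        np.testing.assert_allclose(
            aug.proportions[:, 0] / aug.proportions[:, 1], ratio
        )
        np.testing.assert_allclose(
            norm.proportions[:, 0] / norm.proportions[:, 1], ratio
        )
        # completion closure: rows sum to 1
        np.testing.assert_allclose(aug.proportions.sum(axis=1), 1, atol=1e-9)
        np.testing.assert_allclose(norm.proportions.sum(axis=1), 1, atol=1e-9)


class TestGroupMeans:
    def test_mean_of_identical_rows_is_that_row(self):
        lib = q.PreyLibrary(
            make_matrix([[0.3, 0.7], [0.3, 0.7]], completed=True),
            ["g1", "g1"],
        )
        gm = q.prey_group_means(lib)
        np.testing.assert_allclose(gm.means[0], [0.3, 0.7])

    def test_arithmetic_mean(self):
        lib = q.PreyLibrary(
            make_matrix([[0.2, 0.8], [0.4, 0.6], [0.5, 0.5]],
                        completed=True),
            ["g1", "g1", "g2"],
        )
        gm = q.prey_group_means(lib)
        np.testing.assert_allclose(gm.means[0], [0.3, 0.7])
        assert gm.sizes == [2, 1]
        np.testing.assert_allclose(gm.means.sum(axis=1), 1.0)


class TestCalibrationTransforms:
    def test_unit_cc_is_identity(self):
        p = np.array([0.2, 0.3, 0.5])
        np.testing.assert_allclose(q.to_prey_space(p, np.ones(3)), p)
        np.testing.assert_allclose(q.to_predator_space(p, np.ones(3)), p)

    def test_hand_examples(self):
        np.testing.assert_allclose(
            q.to_prey_space([2 / 3, 1 / 3], [2.0, 1.0]), [0.5, 0.5]
        )
        np.testing.assert_allclose(
            q.to_predator_space([0.5, 0.5], [2.0, 1.0]), [2 / 3, 1 / 3]
        )

    @given(_positive_rows(k=5, n=1), st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_round_trip_and_scale_invariance(self, rows, lam):
        p = np.asarray(rows[0])
        p = p / p.sum()
        c = np.linspace(0.5, 2.0, p.size)
        back = q.to_prey_space(q.to_predator_space(p, c), c)
        np.testing.assert_allclose(back, p, atol=1e-12)
        np.testing.assert_allclose(
            q.to_prey_space(p, lam * c), q.to_prey_space(p, c), atol=1e-12
        )

    def test_zero_proportion_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            q.to_prey_space(np.array([0.0, 1.0]), np.ones(2))


class TestAugmentedCC:
    def _cc(self, coeffs, names=None):
        names = names or [f"fa_{i}" for i in range(len(coeffs))]
        return q.CalibrationVector(names, np.asarray(coeffs, float))

    def test_constant_excluded_coefficients(self):
        cc = self._cc([1.2, 0.8, 2.0, 2.0])
        mean = np.array([0.4, 0.4, 0.15, 0.05])
        assert q.augmented_cc(cc, mean, ["fa_0", "fa_1"]) == pytest.approx(2.0)

    def test_weighted_mean(self):
        cc = self._cc([0.5, 0.5, 1.0, 3.0])
        mean = np.array([0.48, 0.48, 0.01, 0.03])
        # (1*0.01 + 3*0.03) / 0.04 = 2.5
        assert q.augmented_cc(cc, mean, ["fa_0", "fa_1"]) == pytest.approx(2.5)

    def test_empty_excluded_set_fails(self):
        cc = self._cc([1.0, 1.0])
        with pytest.raises(ValueError, match="no excluded"):
            q.augmented_cc(cc, np.array([0.5, 0.5]), ["fa_0", "fa_1"])


class TestMethodConfig:
    def test_joint_model_forces_predator_space(self):
        with pytest.raises(ValueError, match="predator space"):
            q.MethodConfig("joint", "prey", "aitchison", "augment", ["a"])

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            q.MethodConfig("fixed_cc", "prey", "aitchison", "augment", [])
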