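"""Categorical binning, symmetric label encoding and cohort file round-trips."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nutrinet.encoding import (
    Cohort,
    FactorMeta,
    bmi_class,
    encode,
    encode_labels,
    load_cohort,
    quartile_bin,
    save_cohort,
    supplement_bin,
)


class TestQuartileBin:
    def test_known_eight_values(self):
        # quartiles of 1..8 are 2.75 / 4.5 / 6.25 -> two subjects per class
        assert quartile_bin([1, 2, 3, 4, 5, 6, 7, 8]).tolist() == [
            1, 1, 2, 2, 3, 3, 4, 4,
        ]

    def test_boundary_value_goes_to_lower_class(self):
        # 2.75 is exactly q1 of 1..8 -> upper-closed interval keeps it in class 1
        v = [1, 2, 3, 4, 5, 6, 7, 8, 2.75]
        labels = quartile_bin(v)
        q1 = np.quantile(v, 0.25)
        assert labels[-1] == 1 + np.sum(np.array([q1]) < 2.75)

    def test_degenerate_identical_input_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            quartile_bin([0, 0, 0, 0])

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            quartile_bin([1, 2, 3])

    @given(st.permutations(list(range(12))))
    def test_permutation_equivariance(self, perm):
        base = np.arange(12, dtype=float)
        labels = quartile_bin(base)
        assert quartile_bin(base[perm]).tolist() == labels[perm].tolist()

    @given(st.integers(0, 2**31 - 1))
    def test_tie_free_occupancy_near_quarter(self, seed):
        # continuous draws are tie-free, so classes deviate from 25% by <= 1
        v = np.random.default_rng(seed).random(40)
        counts = np.bincount(quartile_bin(v), minlength=5)[1:]
        assert counts.sum() == 40
        assert np.all(np.abs(counts - 10) <= 1)


class TestSupplementBin:
    def test_zero_class_plus_tertiles(self):
        assert supplement_bin([0, 0, 1, 2, 3, 4, 5, 6]).tolist() == [
            1, 1, 2, 2, 3, 3, 4, 4,
        ]

    def test_all_zero_fallback(self):
        assert supplement_bin([0, 0, 0]).tolist() == [1, 1, 1]

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            supplement_bin([0, -1, 2, 3, 4])

    def test_too_few_distinct_nonzero_rejected(self):
        with pytest.raises(ValueError, match="distinct non-zero"):
            supplement_bin([0, 5])

    @given(st.integers(0, 2**31 - 1))
    def test_zeros_and_nonzeros_never_share_classes(self, seed):
        rng = np.random.default_rng(seed)
        v = np.where(rng.random(30) < 0.4, 0.0, rng.lognormal(size=30))
        if np.unique(v[v > 0]).size < 3:
            return
        labels = supplement_bin(v)
        assert np.all(labels[v == 0] == 1)
        assert np.all(labels[v > 0] >= 2)


class TestEncodeLabels:
    def test_four_class_values(self):
        assert np.round(encode_labels(4), 3).tolist() == [-1.0, -0.333, 0.333, 1.0]

    @pytest.mark.parametrize(
        "k,expected", [(2, [-1.0, 1.0]), (3, [-1.0, 0.0, 1.0])]
    )
    def test_small_cases(self, k, expected):
        assert encode_labels(k).tolist() == expected

    @pytest.mark.parametrize("k", range(2, 11))
    def test_symmetry_monotone_endpoints(self, k):
        v = encode_labels(k)
        assert v[0] == -1.0 and v[-1] == 1.0
        assert np.all(np.diff(v) > 0)
        assert np.allclose(v, -v[::-1])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            encode_labels(1)


class TestBmiClass:
    @pytest.mark.parametrize(
        "bmi,cls", [(25.0, "C1"), (25.01, "C2"), (18.5, "C1"), (40.0, "C2")]
    )
    def test_dichotomy_at_25(self, bmi, cls):
        assert bmi_class(bmi) == cls

    @pytest.mark.parametrize("bad", [0.0, -3.0, float("nan"), float("inf")])
    def test_invalid_rejected(self, bad):
        with pytest.raises(ValueError):
            bmi_class(bad)


def _toy_cohort():
    factors = [
        FactorMeta("gender", "gender", ("male", "female")),
        FactorMeta("SNP1", "genotype", ("AA", "AG", "GG")),
        FactorMeta("Chol-Food", "nutrition_food", ("1", "2", "3", "4")),
    ]
    values = np.array([[1, 1, 1], [2, 2, 2], [1, 3, 4]])
    outcome = np.array(["C1", "C2", "C2"], dtype=object)
    return Cohort(factors=factors, values=values, outcome=outcome)


class TestCohortIO:
    def test_minimal_round_trip(self, tmp_path):
        c = _toy_cohort()
        save_cohort(c, tmp_path / "c.csv")
        assert load_cohort(tmp_path / "c.csv") == c

    def test_round_trip_on_simulated_cohort(self, tmp_path, planted_cohort):
        result, _ = planted_cohort
        save_cohort(result.cohort, tmp_path / "sim.tsv")
        assert load_cohort(tmp_path / "sim.tsv") == result.cohort

    def test_missing_cell_reported_with_location(self, tmp_path):
        save_cohort(_toy_cohort(), tmp_path / "c.csv")
        lines = (tmp_path / "c.csv").read_text().splitlines()
        lines[2] = lines[2].replace("AG", "")
        (tmp_path / "c.csv").write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="row 1.*SNP1"):
            load_cohort(tmp_path / "c.csv")

    def test_missing_cell_drop_policy(self, tmp_path):
        save_cohort(_toy_cohort(), tmp_path / "c.csv")
        lines = (tmp_path / "c.csv").read_text().splitlines()
        lines[2] = lines[2].replace("AG", "")
        (tmp_path / "c.csv").write_text("\n".join(lines) + "\n")
        c = load_cohort(tmp_path / "c.csv", on_missing="drop")
        assert c.n_subjects == 2

    def test_unknown_label_rejected(self, tmp_path):
        save_cohort(_toy_cohort(), tmp_path / "c.csv")
        text = (tmp_path / "c.csv").read_text().replace("AG", "XX")
        (tmp_path / "c.csv").write_text(text)
        with pytest.raises(ValueError, match="unknown class label 'XX'"):
            load_cohort(tmp_path / "c.csv")

    def test_duplicate_factor_name_rejected(self):
        with pytest.raises(ValueError, match="duplicated"):
            Cohort(
                factors=[
                    FactorMeta("a", "gender", ("m", "f")),
                    FactorMeta("a", "gender", ("m", "f")),
                ],
                values=np.ones((2, 2), dtype=int),
                outcome=np.array(["C1", "C2"], dtype=object),
            )

    def test_bmi_outcome_column(self, tmp_path):
        save_cohort(_toy_cohort(), tmp_path / "c.csv")
        import yaml

        meta_path = tmp_path / "c.csv.meta.yaml"
        meta = yaml.safe_load(meta_path.read_text())
        meta["outcome_is_bmi"] = True
        meta_path.write_text(yaml.safe_dump(meta))
        text = (tmp_path / "c.csv").read_text()
        text = text.replace("C1", "24.0").replace("C2", "31.5")
        (tmp_path / "c.csv").write_text(text)
        c = load_cohort(tmp_path / "c.csv")
        assert c.outcome.tolist() == ["C1", "C2", "C2"]


class TestEncodeMatrix:
    def test_column_values_per_kind(self):
        mat = encode(_toy_cohort())
        assert set(np.round(mat.X[:, 0], 3)) <= {-1.0, 1.0}  # gender
        assert mat.X[1, 1] == 0.0  # 3-class middle -> 0
        assert mat.X[1, 2] == pytest.approx(-1 / 3)  # 4-class class 2
        assert mat.y.tolist() == [0, 1, 1]

    def test_values_bounded_and_class_counts(self, planted_cohort):
        result, mat = planted_cohort
        assert np.all(mat.X >= -1.0) and np.all(mat.X <= 1.0)
        for j, f in enumerate(result.cohort.factors):
            assert np.unique(mat.X[:, j]).size <= f.n_classes
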