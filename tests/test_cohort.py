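"""Subject selection, stratified splitting, and preprocessing."""

import numpy as np
import pandas as pd
import pytest

from mcishapley import (
    apply_selection_criteria,
    cohort_summary,
    etiv_normalize,
    fit_standardizer,
    generate_visit_table,
    schema,
    stratified_split,
)


def visits_from(histories: dict[str, list[tuple[int, str]]], mri=True) -> pd.DataFrame:
    rows = []
    for sid, visits in histories.items():
        for month, dx in visits:
            rows.append((sid, month, dx, mri if isinstance(mri, bool) else mri[sid]))
    return pd.DataFrame(
        rows, columns=["subject_id", "visit_month", "diagnosis", "mri_available_at_baseline"]
    )


class TestSelection:
    @pytest.mark.parametrize(
        "history, expected",
        [
            ([(0, "MCI"), (12, "MCI"), (24, "MCI")], "sMCI"),
            ([(0, "MCI"), (12, "AD"), (24, "AD")], "pMCI"),
            ([(0, "MCI"), (6, "MCI"), (18, "AD")], "pMCI"),
        ],
        ids=["stable", "converter", "late-converter"],
    )
    def test_labelling_definitions(self, history, expected):
        labels, _ = apply_selection_criteria(visits_from({"A": history}))
        assert labels["A"] == expected

    @pytest.mark.parametrize(
        "history, criterion",
        [
            ([(0, "CN"), (12, "CN")], "no MCI diagnosis at baseline"),
            ([(0, "AD"), (12, "AD")], "no MCI diagnosis at baseline"),
            ([(0, "MCI")], "no follow-up diagnosis"),
            ([(0, "MCI"), (12, "AD"), (24, "MCI")], "diagnosis reverted at a follow-up visit"),
            ([(0, "MCI"), (12, "CN")], "diagnosis reverted at a follow-up visit"),
            ([(0, "MCI"), (6, "AD"), (12, "CN")], "diagnosis reverted at a follow-up visit"),
        ],
        ids=["cn-baseline", "ad-baseline", "no-followup", "ad-to-mci", "mci-to-cn", "ad-to-cn"],
    )
    def test_exclusion_criteria(self, history, criterion):
        labels, report = apply_selection_criteria(visits_from({"A": history}))
        assert "A" not in labels.index
        by_criterion = {c: e for c, e, _ in report.steps}
        assert by_criterion[criterion] == 1

    def test_missing_baseline_mri_excluded(self):
        table = visits_from({"A": [(0, "MCI"), (12, "MCI")]}, mri=False)
        labels, report = apply_selection_criteria(table)
        assert len(labels) == 0
        assert report.steps[-1][1] == 1  # last criterion: no baseline MRI

    def test_missing_baseline_visit_raises(self):
        table = visits_from({"A": [(6, "MCI"), (12, "MCI")]})
        with pytest.raises(ValueError, match="baseline"):
            apply_selection_criteria(table)

    def test_report_counts_are_consistent(self, small_config):
        visits = generate_visit_table(small_config)
        labels, report = apply_selection_criteria(visits)
        remaining = report.n_initial
        for _, excluded, after in report.steps:
            remaining -= excluded
            assert after == remaining
        assert report.n_final == len(labels)
        assert sum(report.class_counts.values()) == len(labels)

    def test_row_order_independence(self, small_config):
        visits = generate_visit_table(small_config)
        shuffled = visits.sample(frac=1.0, random_state=0)
        a, _ = apply_selection_criteria(visits)
        b, _ = apply_selection_criteria(shuffled)
        pd.testing.assert_series_equal(a, b)


class TestStratifiedSplit:
    def test_reproduces_published_totals(self):
        labels = pd.Series(["sMCI"] * 400 + ["pMCI"] * 319)
        split = stratified_split(labels, seed=0)
        counts = split.counts()
        assert (counts["train"], counts["valid"], counts["test"]) == (467, 108, 144)

    def test_per_class_counts_follow_rounding_rule(self):
        labels = pd.Series(["sMCI"] * 400 + ["pMCI"] * 319)
        split = stratified_split(labels, seed=1)
        per_class = pd.crosstab(labels, split.assignment)
        assert per_class.loc["sMCI", ["train", "valid", "test"]].tolist() == [260, 60, 80]
        assert per_class.loc["pMCI", ["train", "valid", "test"]].tolist() == [207, 48, 64]

    def test_exact_fraction_arithmetic(self):
        labels = pd.Series(["sMCI"] * 100 + ["pMCI"] * 100)
        counts = stratified_split(labels, seed=2).counts()
        assert (counts["train"], counts["valid"], counts["test"]) == (130, 30, 40)

    def test_partitions_disjoint_exhaustive_and_reproducible(self):
        rng = np.random.default_rng(3)
        labels = pd.Series(
            rng.choice(["sMCI", "pMCI"], size=173),
            index=[f"S{i}" for i in range(173)],
        )
        a = stratified_split(labels, seed=5)
        b = stratified_split(labels, seed=5)
        pd.testing.assert_series_equal(a.assignment, b.assignment)
        parts = [set(a.ids(p)) for p in ("train", "valid", "test")]
        assert sum(len(p) for p in parts) == len(labels)
        assert set().union(*parts) == set(labels.index)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            stratified_split(pd.Series(["sMCI", "pMCI"]), fractions=(0.6, 0.3, 0.3))


class TestEtivNormalize:
    def _table(self, volume, etiv):
        cols = schema.regional_volume_columns()
        df = pd.DataFrame({schema.SUBJECT_ID: ["A"]})
        for c in cols:
            df[c] = volume
        df[schema.ETIV] = etiv
        return df.copy()

    def test_simple_division(self):
        out = etiv_normalize(self._table(8000.0, 1.6e6))
        assert out["Left-Hippocampus"].iloc[0] == pytest.approx(0.005)
        assert out[schema.ETIV].iloc[0] == 1.6e6  # eTIV retained raw

    def test_ratio_invariance_under_global_scaling(self):
        a = etiv_normalize(self._table(8000.0, 1.6e6))
        b = etiv_normalize(self._table(16000.0, 3.2e6))
        regional = schema.regional_volume_columns()
        pd.testing.assert_frame_equal(a[regional], b[regional])

    def test_feature_count_is_103(self):
        out = etiv_normalize(self._table(8000.0, 1.6e6))
        assert len([c for c in schema.volumetric_columns() if c in out.columns]) == 103

    def test_nonpositive_etiv_names_subject(self):
        with pytest.raises(ValueError, match="subject A"):
            etiv_normalize(self._table(8000.0, 0.0))


class TestStandardizer:
    def test_two_point_example(self):
        train = pd.DataFrame({"f": [-1.0, 1.0]})
        st = fit_standardizer(train)
        assert st.center["f"] == 0.0
        assert st.scale["f"] == 1.0
        assert st.transform(pd.DataFrame({"f": [3.0]}))["f"].iloc[0] == 3.0

    def test_training_rows_become_mean0_sd1(self):
        rng = np.random.default_rng(0)
        train = pd.DataFrame(rng.normal(5, 3, size=(50, 4)), columns=list("abcd"))
        st = fit_standardizer(train)
        z = st.transform(train)
        assert np.abs(z.mean().to_numpy()).max() < 1e-10
        assert np.abs(z.std(ddof=0).to_numpy() - 1).max() < 1e-10

    def test_other_partition_mean_not_zero(self):
        train = pd.DataFrame({"f": [0.0, 1.0, 2.0]})
        valid = pd.DataFrame({"f": [5.0, 6.0, 7.0]})
        st = fit_standardizer(train)
        assert abs(st.transform(valid)["f"].mean()) > 1.0

    def test_round_trip_identity(self):
        rng = np.random.default_rng(1)
        train = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("xyz"))
        st = fit_standardizer(train)
        back = st.inverse_transform(st.transform(train))
        assert np.abs((back - train).to_numpy()).max() < 1e-10

    def test_zero_variance_feature_named(self):
        train = pd.DataFrame({"ok": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            fit_standardizer(train)


class TestCohortSummary:
    def _toy(self):
        features = pd.DataFrame(
            {
                schema.SUBJECT_ID: [f"S{i}" for i in range(8)],
                "age": [70, 71, 72, 73, 80, 81, 82, 83],
                "MMSE": [29, 29, 28, 28, 24, 24, 23, 23],
                "LDELTOTAL": [10, 11, 12, 13, 3, 2, 1, 0],
                "LIMMTOTAL": [12, 12, 13, 13, 5, 5, 4, 4],
                "gender": ["female", "male"] * 4,
                "apoe4_count": [0, 0, 0, 0, 1, 1, 1, 1],
            }
        )
        labels = pd.Series(
            ["sMCI"] * 4 + ["pMCI"] * 4, index=features[schema.SUBJECT_ID]
        )
        return features, labels

    def test_identical_categorical_distribution_gives_p_one(self):
        features, labels = self._toy()
        out = cohort_summary(features, labels, continuous=(), categorical=("gender",))
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_separated_continuous_gives_small_p(self):
        features, labels = self._toy()
        out = cohort_summary(features, labels, continuous=("LDELTOTAL",), categorical=())
        assert out["p_value"].iloc[0] < 0.05

    def test_table_layout(self, clean_config):
        from mcishapley import generate_feature_table

        visits = generate_visit_table(clean_config)
        labels, _ = apply_selection_criteria(visits)
        features = generate_feature_table(clean_config, labels)
        out = cohort_summary(features, labels)
        assert {"variable", "type", "sMCI", "pMCI", "p_value"} <= set(out.columns)
        assert (out["type"] == "continuous").sum() == 4
        assert out["variable"].str.startswith("apoe4_count").sum() == 3
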