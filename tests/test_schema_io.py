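"""Schema, CSV reading, exclusion filters, imputation and quartile binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lacthresh as lt
from lacthresh import schema as sc
from lacthresh.cohort import (
    CohortTable, ExclusionCriteria, QuartileBinning, apply_exclusions,
    group_sizes, impute_median, quartile_bin, read_cohort,
)
from lacthresh.errors import (
    DegenerateBinningError, SchemaError, UnimputableError, ValidationError,
)

MINI_SCHEMA = [
    sc.VariableSchema("lactate", "exposure", "continuous", "mmol/L", "median_iqr"),
    sc.VariableSchema("mortality_28d", "outcome", "binary", "", "count_pct"),
    sc.VariableSchema("age", "covariate", "continuous", "years", "mean_sd"),
]


def write_csv(tmp_path, text, name="cohort.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


@pytest.mark.parametrize("suffix", [".yaml", ".json"])
def test_schema_roundtrip_through_file(tmp_path, suffix):
    path = tmp_path / f"schema{suffix}"
    sc.save_schema(sc.default_schema(), path)
    loaded = sc.load_schema(path)
    assert loaded == sc.default_schema()


def test_schema_invariants_enforced():
    with pytest.raises(SchemaError):
        sc.validate_schema([MINI_SCHEMA[0]])  # no outcome
    with pytest.raises(SchemaError):
        sc.validate_schema(MINI_SCHEMA + [MINI_SCHEMA[0]])  # two exposures


class TestReadCohort:
    def test_reads_and_types_a_small_file(self, tmp_path):
        p = write_csv(tmp_path, "lactate,mortality_28d,age\n"
                                "1.2,0,70\n2.5,1,80\n0.9,0,66\n3.3,1,91\n1.1,0,77\n")
        t = read_cohort(p, MINI_SCHEMA)
        assert t.n == 5
        assert t.df["lactate"].dtype == float
        assert t.df["mortality_28d"].tolist() == [0, 1, 0, 1, 0]

    def test_outcome_outside_binary_rejected(self, tmp_path):
        p = write_csv(tmp_path, "lactate,mortality_28d,age\n1.2,2,70\n")
        with pytest.raises(ValidationError):
            read_cohort(p, MINI_SCHEMA)

    @pytest.mark.parametrize("token", ["", "NA", "NaN", "nan"])
    def test_missing_tokens_keep_the_row(self, tmp_path, token):
        p = write_csv(tmp_path, f"lactate,mortality_28d,age\n{token},0,70\n2.0,1,80\n")
        t = read_cohort(p, MINI_SCHEMA)
        assert t.n == 2
        assert t.df["lactate"].isna().tolist() == [True, False]

    def test_missing_required_column_is_schema_error(self, tmp_path):
        p = write_csv(tmp_path, "lactate,age\n1.2,70\n")
        with pytest.raises(SchemaError):
            read_cohort(p, MINI_SCHEMA)


def _exclusion_frame():
    # 10 rows: 2 under-age, 1 short stay, 1 non-sepsis, 1 without lactate
    rows = []
    base = dict(lactate=2.0, mortality_28d=0, age=80.0, icu_los_hours=48.0,
                sepsis=1, lactate_count=1)
    for age in (50, 60):
        rows.append({**base, "age": age})
    rows.append({**base, "icu_los_hours": 10.0})
    rows.append({**base, "sepsis": 0})
    rows.append({**base, "lactate_count": 0})
    rows.extend([dict(base) for _ in range(5)])
    return pd.DataFrame(rows)


EXC_SCHEMA = MINI_SCHEMA + [
    sc.VariableSchema("icu_los_hours", "admin", "continuous", "hours"),
    sc.VariableSchema("sepsis", "admin", "binary"),
    sc.VariableSchema("lactate_count", "admin", "continuous"),
]


class TestExclusions:
    def test_sequential_counts_partition_the_input(self):
        df = _exclusion_frame()
        df["age"] = df["age"].astype(float)
        t = CohortTable(df.assign(age=df.age), EXC_SCHEMA)
        out, removed = apply_exclusions(t)
        assert out.n == 5
        assert list(removed.values()) == [2, 1, 1, 1]
        assert sum(removed.values()) + out.n == 10

    def test_clean_table_removes_nothing(self, cohort_small):
        out, removed = apply_exclusions(cohort_small)
        assert out.n == cohort_small.n
        assert all(v == 0 for v in removed.values())

    def test_disabled_criteria_are_identity(self):
        t = CohortTable(_exclusion_frame(), EXC_SCHEMA)
        out, removed = apply_exclusions(
            t, ExclusionCriteria(min_age=0, min_icu_hours=0,
                                 require_sepsis_flag=False,
                                 min_exposure_measurements=0))
        assert out.n == t.n and removed == {}

    def test_idempotent(self, cohort_small):
        once, _ = apply_exclusions(cohort_small)
        twice, removed = apply_exclusions(once)
        assert removed == {k: 0 for k in removed}
        pd.testing.assert_frame_equal(once.df, twice.df)


class TestImputeMedian:
    def _table(self, col, kind="continuous"):
        df = pd.DataFrame({"lactate": np.linspace(1, 2, len(col)),
                           "mortality_28d": [0] * len(col), "age": col})
        schema = MINI_SCHEMA[:2] + [
            sc.VariableSchema("age", "covariate", kind,
                              summary_style="mean_sd" if kind == "continuous"
                              else "count_pct")]
        return CohortTable(df, schema)

    def test_even_count_median_fills_gap(self):
        t = impute_median(self._table([1.0, 2.0, np.nan, 4.0]))
        assert t.df["age"].tolist() == [1.0, 2.0, 2.0, 4.0]

    def test_complete_column_is_untouched(self):
        before = self._table([1.0, 2.0, 3.0, 4.0])
        after = impute_median(before)
        pd.testing.assert_series_equal(before.df["age"], after.df["age"])

    def test_binary_mode_imputation(self):
        t = impute_median(self._table([0.0, 0.0, 1.0, np.nan], kind="binary"))
        assert t.df["age"].tolist() == [0.0, 0.0, 1.0, 0.0]

    def test_all_missing_column_raises(self):
        with pytest.raises(UnimputableError, match="age"):
            impute_median(self._table([np.nan, np.nan, np.nan]))

    def test_no_missing_covariates_remain(self, cohort_small):
        covs = [v.name for v in cohort_small.schema
                if v.role in ("covariate", "stratifier")]
        assert cohort_small.df[covs].notna().all().all()


class TestQuartileBin:
    def _table(self, x):
        df = pd.DataFrame({"lactate": x, "mortality_28d": np.zeros(len(x)),
                           "age": np.full(len(x), 70.0)})
        return CohortTable(df, MINI_SCHEMA)

    def test_uniform_exposure_splits_evenly(self):
        binning, labels = quartile_bin(self._table(np.arange(1.0, 101.0)))
        assert list(group_sizes(labels).values()) == [25, 25, 25, 25]

    def test_four_tied_blocks_split_evenly(self):
        x = np.repeat([1.0, 2.0, 3.0, 4.0], 25)
        _, labels = quartile_bin(self._table(x))
        assert list(group_sizes(labels).values()) == [25, 25, 25, 25]

    def test_constant_exposure_is_degenerate(self):
        with pytest.raises(DegenerateBinningError):
            quartile_bin(self._table(np.full(20, 2.0)))

    def test_generated_cohort_matches_published_cutpoints(self, cohort_full):
        binning, _ = quartile_bin(cohort_full)
        # oracle: sort-and-index percentiles of the same draws
        x = np.sort(cohort_full.df["lactate"].to_numpy())
        oracle = [x[int(round(q * (len(x) - 1)))] for q in (0.25, 0.5, 0.75)]
        for got, ora in zip(binning.cutpoints, oracle):
            assert got == pytest.approx(ora, abs=0.02)
        for got, published in zip(binning.cutpoints, (1.5, 2.10, 3.27)):
            assert got == pytest.approx(published, abs=0.2)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.1, 50, allow_nan=False), min_size=8, max_size=200,
                    unique=True))
    def test_labels_partition_rows(self, xs):
        _, labels = quartile_bin(self._table(np.array(xs)))
        sizes = list(group_sizes(labels).values())
        assert sum(sizes) == len(xs)
        assert max(sizes) - min(sizes) <= 1 or len(xs) % 4 != 0

    def test_assign_respects_half_open_intervals(self):
        b = QuartileBinning((1.5, 2.0, 3.27))
        assert b.assign(np.array([1.5, 2.0, 3.27, 1.49, 10.0])).tolist() == \
            ["Q2", "Q3", "Q4", "Q1", "Q4"]
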