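"""Data model, long-format round trips, ddCt preprocessing, normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cholestage import (
    DatasetError,
    FactorMeta,
    TimeCourseDataset,
    ddct_normalize,
    normalize_factors,
    read_dataset,
    write_dataset,
)


def _toy_dataset(values=None, n_t=8, n_r=5, seed=0):
    rng = np.random.default_rng(seed)
    times = [0, 6, 12, 18, 30, 48, 120, 336][:n_t]
    if values is None:
        values = rng.normal(size=(3, n_t, n_r))
    factors = [
        FactorMeta("Timp1_like", "transcript", "fibrosis"),
        FactorMeta("bilirubin_like", "B", "none"),
        FactorMeta("ctgf_like", "A", "none"),
    ][: values.shape[0]]
    return TimeCourseDataset(factors, times, values)


class TestDatasetModel:
    def test_grid_dimensions(self):
        data = _toy_dataset()
        assert (data.n_factors, data.n_times, data.n_replicates) == (3, 8, 5)

    @pytest.mark.parametrize(
        "times, err",
        [
            ([6, 12], "first time point"),
            ([0, 12, 12], "strictly increasing"),
            ([0], "at least 2 time points"),
        ],
    )
    def test_invalid_time_grids_rejected(self, times, err):
        with pytest.raises(DatasetError, match=err):
            TimeCourseDataset(
                [FactorMeta("f", "B", "none")],
                times,
                np.zeros((1, len(times), 2)),
            )

    def test_duplicate_factor_ids_rejected(self):
        with pytest.raises(DatasetError, match="duplicate factor ids"):
            TimeCourseDataset(
                [FactorMeta("f", "B", "none"), FactorMeta("f", "H", "none")],
                [0, 6],
                np.zeros((2, 2, 2)),
            )

    def test_transcript_panel_invariants(self):
        with pytest.raises(DatasetError, match="must carry a gene panel"):
            FactorMeta("g", "transcript", "none")
        with pytest.raises(DatasetError, match="panel 'none'"):
            FactorMeta("b", "B", "ADME")

    def test_subset_preserves_order_and_values(self):
        data = _toy_dataset()
        sub = data.subset(["ctgf_like", "Timp1_like"])
        assert sub.factor_ids == ["ctgf_like", "Timp1_like"]
        np.testing.assert_array_equal(
            sub.factor_values("ctgf_like"), data.factor_values("ctgf_like")
        )


class TestLongFormatIO:
    def test_round_trip(self, tmp_path):
        data = _toy_dataset(seed=5)
        path = tmp_path / "d.csv"
        write_dataset(data, path)
        back = read_dataset(path)
        assert back.factor_ids == data.factor_ids
        np.testing.assert_array_equal(back.times, data.times)
        np.testing.assert_array_equal(back.values, data.values)
        assert [f.modality for f in back.factors] == [
            f.modality for f in data.factors
        ]

    def test_duplicate_triple_rejected(self, tmp_path):
        data = _toy_dataset()
        df = data.to_frame()
        df = pd.concat([df, df.iloc[[7]]])
        path = tmp_path / "dup.csv"
        df.to_csv(path, index=False)
        row = df.iloc[7]
        with pytest.raises(DatasetError) as exc:
            read_dataset(path)
        msg = str(exc.value)
        assert row.factor_id in msg and str(row.time_h) in msg

    def test_absent_cell_flagged_missing(self, tmp_path):
        data = _toy_dataset()
        df = data.to_frame()
        dropped = df.iloc[13]
        df = df.drop(index=13)
        path = tmp_path / "gap.csv"
        df.to_csv(path, index=False)
        with pytest.warns(UserWarning, match="missing"):
            back = read_dataset(path)
        block = back.factor_values(dropped.factor_id)
        i = list(back.times).index(dropped.time_h)
        assert np.isnan(block[i, int(dropped.replicate) - 1])
        assert back.missing_mask.sum() == 1

    def test_malformed_value_names_line(self, tmp_path):
        data = _toy_dataset()
        df = data.to_frame().astype({"value": object})
        df.loc[4, "value"] = "not-a-number"
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(DatasetError, match="line 6"):
            read_dataset(path)


class TestDdct:
    def test_gene_equal_to_reference_gives_unity(self):
        ct = pd.DataFrame(
            {
                "gene": ["g1"] * 4 + ["Gapdh"] * 4,
                "sample": ["s1", "s2", "s3", "s4"] * 2,
                "ct": [20, 21, 22, 23] * 2,
            }
        )
        out = ddct_normalize(ct, "Gapdh", ["s1"])
        np.testing.assert_allclose(out["rel_expr"], 1.0)

    def test_hand_computed_two_gene_table(self):
        # dCt(g1) = (25,24,26,23) - (20,20,21,20) = (5,4,5,3)
        # controls s1,s2: mean dCt(g1) = 4.5 -> ddCt = (0.5,-0.5,0.5,-1.5)
        # dCt(g2) = (18,19,17,16) - ref = (-2,-1,-4,-4); ctrl mean -1.5
        # -> ddCt(g2) = (-0.5, 0.5, -2.5, -2.5)
        ct = pd.DataFrame(
            {
                "gene": ["g1"] * 4 + ["g2"] * 4 + ["Gapdh"] * 4,
                "sample": ["s1", "s2", "s3", "s4"] * 3,
                "ct": [25, 24, 26, 23, 18, 19, 17, 16, 20, 20, 21, 20],
            }
        )
        out = ddct_normalize(ct, "Gapdh", ["s1", "s2"]).set_index(
            ["gene", "sample"]
        )["rel_expr"]
        expected = {
            ("g1", "s1"): 2.0**-0.5,
            ("g1", "s2"): 2.0**0.5,
            ("g1", "s3"): 2.0**-0.5,
            ("g1", "s4"): 2.0**1.5,
            ("g2", "s1"): 2.0**0.5,
            ("g2", "s2"): 2.0**-0.5,
            ("g2", "s3"): 2.0**2.5,
            ("g2", "s4"): 2.0**2.5,
        }
        for key, val in expected.items():
            assert out[key] == pytest.approx(val)

    def test_control_group_geometric_mean_is_one(self):
        rng = np.random.default_rng(2)
        samples = [f"s{i}" for i in range(6)]
        ct = pd.DataFrame(
            {
                "gene": ["g"] * 6 + ["ref"] * 6,
                "sample": samples * 2,
                "ct": rng.uniform(18, 30, 12),
            }
        )
        out = ddct_normalize(ct, "ref", ["s0", "s1", "s2"])
        ctrl = out[out["sample"].isin(["s0", "s1", "s2"])]["rel_expr"]
        assert np.exp(np.log(ctrl).mean()) == pytest.approx(1.0)
        assert (out["rel_expr"] > 0).all()

    def test_missing_reference_and_nonfinite_ct(self):
        ct = pd.DataFrame(
            {
                "gene": ["g", "g", "ref"],
                "sample": ["s1", "s2", "s1"],
                "ct": [20, 21, 19],
            }
        )
        with pytest.raises(DatasetError, match="reference gene"):
            ddct_normalize(ct, "ref", ["s1"])
        ct2 = pd.DataFrame(
            {
                "gene": ["g", "g", "ref", "ref"],
                "sample": ["s1", "s2", "s1", "s2"],
                "ct": [20, np.inf, 19, 19],
            }
        )
        out = ddct_normalize(ct2, "ref", ["s1"])
        assert np.isnan(
            out.set_index("sample").loc["s2", "rel_expr"]
        )


class TestNormalization:
    def test_two_value_factor(self):
        data = _toy_dataset(
            values=np.array([[[0.0, 0.0], [1.0, 1.0]]]), n_t=2, n_r=2
        )
        out = normalize_factors(data)
        np.testing.assert_allclose(
            out.factor_values("Timp1_like"), [[-0.5, -0.5], [0.5, 0.5]]
        )

    def test_mean_zero_range_one(self):
        data = _toy_dataset(seed=9)
        out = normalize_factors(data)
        for f in out.factor_ids:
            block = out.factor_values(f)
            assert abs(block.mean()) < 1e-9
            assert np.ptp(block) == pytest.approx(1.0, abs=1e-9)

    @settings(derandomize=True, max_examples=40)
    @given(
        a=st.floats(0.01, 100.0),
        b=st.floats(-50.0, 50.0),
    )
    def test_positive_affine_invariance(self, a, b):
        data = _toy_dataset(seed=1)
        scaled = TimeCourseDataset(
            list(data.factors), data.times, a * data.values + b
        )
        np.testing.assert_allclose(
            normalize_factors(scaled).values,
            normalize_factors(data).values,
            atol=1e-12,
        )

    def test_idempotent(self):
        data = _toy_dataset(seed=4)
        once = normalize_factors(data)
        twice = normalize_factors(once)
        assert np.abs(twice.values - once.values).max() < 1e-9

    def test_constant_factor_named_in_error(self):
        vals = np.random.default_rng(0).normal(size=(3, 8, 5))
        vals[1] = 7.0
        data = _toy_dataset(values=vals)
        with pytest.raises(DatasetError, match="bilirubin_like"):
            normalize_factors(data)

    def test_missing_cells_stay_missing(self):
        vals = np.random.default_rng(0).normal(size=(3, 8, 5))
        vals[0, 2, 3] = np.nan
        out = normalize_factors(_toy_dataset(values=vals))
        assert np.isnan(out.values[0, 2, 3])
        assert np.isnan(out.values).sum() == 1
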