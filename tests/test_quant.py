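import numpy as np
import pandas as pd
import pytest

from lncfat.quant import (
    call_specificity,
    compute_fpkm,
    ddct,
    differential_screen,
    filter_expressed,
)

SAMPLES = ["LT1", "LT2", "LT3", "ST1", "ST2", "ST3"]
TISSUES = pd.Series({s: s[:2] for s in SAMPLES})


def matrix(counts_dict, lengths, samples=None):
    samples = samples or SAMPLES
    counts = pd.DataFrame(counts_dict, index=samples).T
    return compute_fpkm(counts, pd.Series(lengths), TISSUES.loc[samples])


class TestFpkm:
    def test_closed_form(self):
        # library total 1e6, length 1 kb, 10 fragments -> FPKM 10
        m = matrix(
            {"a": [10] * 6, "filler": [1_000_000 - 10] * 6},
            {"a": 1_000, "filler": 1_000},
        )
        assert np.allclose(m.fpkm.loc["a"], 10.0)

    def test_zero_counts_zero_fpkm(self):
        m = matrix({"a": [0] * 6, "b": [5] * 6}, {"a": 100, "b": 100})
        assert (m.fpkm.loc["a"] == 0).all()
        assert (m.fpkm.loc["b"] > 0).all()

    def test_scale_invariance(self):
        c1 = {"a": [10] * 6, "b": [90] * 6}
        m1 = matrix(c1, {"a": 500, "b": 500})
        m2 = matrix({k: [3 * v for v in vals] for k, vals in c1.items()},
                    {"a": 500, "b": 500})
        assert np.allclose(m1.fpkm, m2.fpkm)

    def test_zero_library_total_names_sample(self):
        counts = pd.DataFrame(
            {"LT1": [0, 0], "LT2": [1, 1], "LT3": [1, 1],
             "ST1": [1, 1], "ST2": [1, 1], "ST3": [1, 1]},
            index=["a", "b"],
        )
        with pytest.raises(ValueError, match="LT1"):
            compute_fpkm(counts, pd.Series({"a": 100, "b": 100}), TISSUES)

    def test_bad_length_and_negative_counts(self):
        with pytest.raises(ValueError, match="length"):
            matrix({"a": [1] * 6}, {"a": 0})
        counts = pd.DataFrame({s: [-1] for s in SAMPLES}, index=["a"])
        with pytest.raises(ValueError, match="nonnegative"):
            compute_fpkm(counts, pd.Series({"a": 100}), TISSUES)


class TestExpressionFilter:
    def test_threshold_rules(self):
        total = 200_000_000  # library total per sample, by construction
        counts = pd.DataFrame(
            {
                "low": [1] * 6,          # FPKM 0.005 everywhere
                "one_sample": [0, 0, 0, 90, 0, 0],  # FPKM 0.15 in ST1 only
                "boundary": [20] * 6,    # FPKM exactly 0.1
            },
            index=SAMPLES,
        ).T
        counts.loc["big"] = total - counts.sum(axis=0)
        m = compute_fpkm(counts, pd.Series(
            {"low": 1000, "one_sample": 3000, "boundary": 1000, "big": 1000}),
            TISSUES)
        assert np.isclose(m.fpkm.loc["boundary"].max(), 0.1)
        kept = filter_expressed(m).features
        assert "low" not in kept          # below threshold everywhere
        assert "one_sample" in kept       # > 0.1 in a single sample suffices
        assert "boundary" not in kept     # exactly 0.1 fails the strict >
        assert "big" in kept


class TestDifferentialScreen:
    def test_null_feature_is_ns(self):
        m = matrix({"a": [5, 6, 7, 5, 6, 7], "b": [100] * 6},
                   {"a": 1000, "b": 1000})
        de = differential_screen(m)
        assert de.loc["a", "status"] == "ns"
        assert de.loc["a", "log2fc"] == pytest.approx(0.0, abs=1e-9)

    def test_fold_change_formula_with_pseudocount(self):
        # engineer mean FPKM 1 in LT and 9 in ST for feature "a"
        lt, st = 100, 900
        filler_lt, filler_st = 10**8 - lt, 10**8 - st
        counts = pd.DataFrame(
            {s: [lt if s.startswith("LT") else st,
                 filler_lt if s.startswith("LT") else filler_st]
             for s in SAMPLES},
            index=["a", "filler"],
        )
        m = compute_fpkm(counts, pd.Series({"a": 1000, "filler": 1000}), TISSUES)
        assert m.fpkm.loc["a", "LT1"] == pytest.approx(1.0)
        de = differential_screen(m)
        assert de.loc["a", "log2fc"] == pytest.approx(np.log2(10 / 2), rel=1e-6)

    def test_status_partition(self, small_dataset):
        m = compute_fpkm(small_dataset.counts, small_dataset.effective_lengths,
                         small_dataset.tissues)
        de = differential_screen(m)
        counts = de["status"].value_counts()
        assert counts.sum() == len(de)
        assert set(counts.index) <= {"up", "down", "ns"}

    def test_planted_fourfold_recovered(self):
        """Planted 4-fold features at low dispersion are called up/down."""
        rng = np.random.default_rng(42)
        n, planted = 200, 40
        mu = np.full(n, 500.0)
        fc = np.ones(n)
        fc[:planted // 2] = 4.0
        fc[planted // 2:planted] = 0.25
        phi = 0.01
        lam_lt = np.tile(mu[:, None], 3)
        lam_st = np.tile((mu * fc)[:, None], 3)
        lam = np.concatenate([lam_lt, lam_st], axis=1)
        counts = rng.negative_binomial(1 / phi, (1 / phi) / (1 / phi + lam))
        cdf = pd.DataFrame(counts, index=[f"f{i}" for i in range(n)],
                           columns=SAMPLES)
        m = compute_fpkm(cdf, pd.Series(1000.0, index=cdf.index), TISSUES)
        de = differential_screen(m)
        up = de.iloc[:planted // 2]["status"] == "up"
        down = de.iloc[planted // 2:planted]["status"] == "down"
        sensitivity = (up.sum() + down.sum()) / planted
        assert sensitivity >= 0.9

    def test_log2fc_parameter_recovery(self):
        """Planted |log2FC| = 2 (sign-balanced) is recovered with MAE < 0.5."""
        rng = np.random.default_rng(3)
        n, phi = 200, 0.05
        true_lfc = np.zeros(n)
        true_lfc[:25], true_lfc[25:50] = 2.0, -2.0  # balanced, so FPKM
        mu = np.full(n, 500.0)                      # totals stay comparable
        lam = np.concatenate(
            [np.tile(mu[:, None], 3),
             np.tile((mu * 2.0**true_lfc)[:, None], 3)], axis=1)
        counts = rng.negative_binomial(1 / phi, (1 / phi) / (1 / phi + lam))
        cdf = pd.DataFrame(counts, index=[f"f{i}" for i in range(n)],
                           columns=SAMPLES)
        m = compute_fpkm(cdf, pd.Series(1000.0, index=cdf.index), TISSUES)
        de = differential_screen(m)
        mae = (de["log2fc"].to_numpy()[:50] - true_lfc[:50]).__abs__().mean()
        assert mae < 0.5

    def test_too_few_replicates_error(self):
        counts = pd.DataFrame({"LT1": [5], "ST1": [5], "ST2": [6]}, index=["a"])
        with pytest.raises(ValueError, match="2 samples"):
            differential_screen(
                compute_fpkm(counts, pd.Series({"a": 100}),
                             TISSUES.loc[["LT1", "ST1", "ST2"]]))

    def test_external_pvalues_plug_in(self):
        m = matrix({"a": [1, 1, 1, 100, 100, 100], "b": [50] * 6},
                   {"a": 1000, "b": 1000})
        forced = pd.Series({"a": 1.0, "b": 1.0})
        de = differential_screen(m, pvalues=forced)
        assert (de["status"] == "ns").all()


class TestSpecificity:
    def test_labels(self):
        counts = pd.DataFrame(
            {
                "st_only": [0, 0, 0, 1000, 2000, 3000],
                "lt_only": [1000, 500, 800, 0, 0, 0],
                "both": [500] * 6,
                "silent": [0] * 6,
                "filler": [10**6] * 6,
            },
            index=SAMPLES,
        ).T
        m = compute_fpkm(counts, pd.Series(1000.0, index=counts.index), TISSUES)
        spec = call_specificity(m)
        assert spec["st_only"] == "ST_specific"
        assert spec["lt_only"] == "LT_specific"
        assert spec["both"] == "shared"
        assert spec["silent"] == "not_expressed"


class TestDdct:
    def test_identity(self):
        assert ddct(20, 15, 25, 20) == pytest.approx(1.0)

    def test_closed_form(self):
        # ddCt = (20-15) - (22-15) = -2 -> 2^2 = 4
        assert ddct(20, 15, 22, 15) == pytest.approx(4.0)

    def test_monotone_halving(self):
        base = ddct(20, 15, 22, 15)
        assert ddct(21, 15, 22, 15) == pytest.approx(base / 2)

    def test_nonfinite_ct_rejected(self):
        with pytest.raises(ValueError):
            ddct(float("nan"), 15, 22, 15)
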