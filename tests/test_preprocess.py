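"""Replicate filtering, antibody QC, collapse, z-scaling, consistency."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adaptsig import preprocess, simulate
from adaptsig.preprocess import (assemble_design, antibody_qc,
                                 collapse_log2fc, consistency_mask,
                                 iqr_outlier_filter)
from conftest import make_tensor, run_signal_pipeline


class TestIQRFilter:
    def test_equal_values_all_retained(self):
        out = iqr_outlier_filter([5] * 8)
        assert list(out) == [5] * 8

    def test_hand_computed_fence_removes_single_outlier(self):
        # Q1=2, Q3=3.25 (type-7 quantiles), upper fence 5.125 -> 10 removed
        out = iqr_outlier_filter([1, 2, 2, 3, 3, 3, 4, 10])
        assert sorted(out) == [1, 2, 2, 3, 3, 3, 4]

    def test_singleton_passes_through(self):
        assert list(iqr_outlier_filter([3.7])) == [3.7]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            iqr_outlier_filter([])

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6,
                              allow_nan=False), min_size=1, max_size=16))
    def test_idempotent_and_median_survives(self, values):
        once = iqr_outlier_filter(values)
        twice = iqr_outlier_filter(once)
        assert list(once) == list(twice)
        assert len(once) >= 1
        assert set(np.round(once, 12)) <= set(np.round(values, 12))


def _qc_tensor(rng, n_conditions=200, n_bio=4, noise=0.05,
               scramble_ab=None):
    """Three-antibody tensor; optionally one antibody pure noise."""
    rows = []
    for ab in ("ab1", "ab2", "ab3"):
        base = rng.normal(10, 1, size=n_conditions)
        for c in range(n_conditions):
            for b in range(n_bio):
                val = (rng.normal(10, 1) if ab == scramble_ab
                       else base[c] + rng.normal(0, noise))
                rows.append(("CL", "drug", float(c + 1), 1.0, ab,
                             b + 1, 1, "A", 2.0 ** val))
    return pd.DataFrame(rows, columns=[
        "cell_line", "drug", "dose", "time", "antibody",
        "bio_rep", "tech_rep", "scanner", "value"])


class TestAntibodyQC:
    def test_identical_replicates_score_one(self):
        rng = np.random.default_rng(0)
        tensor = _qc_tensor(rng, n_conditions=30, noise=0.0)
        retained, scores = antibody_qc(tensor, "CL")
        assert set(retained) == {"ab1", "ab2", "ab3"}
        np.testing.assert_allclose(scores["score"], 1.0, atol=1e-12)

    def test_noise_antibody_dropped(self):
        rng = np.random.default_rng(1)
        tensor = _qc_tensor(rng, scramble_ab="ab2")
        retained, scores = antibody_qc(tensor, "CL", threshold=0.5)
        assert "ab2" not in retained
        assert {"ab1", "ab3"} <= set(retained)
        assert abs(scores.loc["ab2", "score"]) < 0.3

    def test_threshold_one_with_noise_drops_everything(self):
        rng = np.random.default_rng(2)
        tensor = _qc_tensor(rng, noise=0.2)
        retained, scores = antibody_qc(tensor, "CL", threshold=1.0)
        assert retained == []

    def test_insufficient_replicates_flagged_and_retained(self):
        rng = np.random.default_rng(3)
        tensor = _qc_tensor(rng, n_conditions=20)
        solo = tensor[tensor["antibody"] == "ab1"]
        tensor = pd.concat([tensor[tensor["antibody"] != "ab1"],
                            solo[solo["bio_rep"] == 1]])
        retained, scores = antibody_qc(tensor, "CL")
        assert scores.loc["ab1", "insufficient"]
        assert "ab1" in retained

    def test_single_bio_rep_rejected(self):
        rng = np.random.default_rng(4)
        tensor = _qc_tensor(rng, n_conditions=10, n_bio=1)
        with pytest.raises(ValueError):
            antibody_qc(tensor, "CL")


class TestCollapse:
    def test_treated_equal_to_control_gives_zero(self):
        tensor = make_tensor({("DMSO", 0.0): [8, 8, 8, 8],
                              ("drug", 1.0): [8, 8, 8, 8]})
        fc = collapse_log2fc(tensor)
        treated = fc[fc["dose"] > 0]["log2fc"]
        np.testing.assert_allclose(treated, 0.0, atol=1e-12)

    def test_fourfold_increase_gives_two(self):
        tensor = make_tensor({("DMSO", 0.0): [8, 8, 8, 8],
                              ("drug", 1.0): [32, 32, 32, 32]})
        fc = collapse_log2fc(tensor)
        assert fc[fc["dose"] > 0]["log2fc"].iloc[0] == pytest.approx(2.0)

    def test_control_rows_map_to_zero(self):
        tensor = make_tensor({("DMSO", 0.0): [8, 9, 10, 11],
                              ("drug", 1.0): [16, 16, 16, 16]})
        fc = collapse_log2fc(tensor)
        assert (fc[fc["dose"] == 0]["log2fc"] == 0).all()

    def test_outlier_replicate_removed_before_median(self):
        # without the IQR filter the median of the treated set would shift
        tensor = make_tensor({("DMSO", 0.0): [8.0] * 8,
                              ("drug", 1.0): [16, 16, 16, 16, 16, 16, 16,
                                              16000.0]})
        fc = collapse_log2fc(tensor)
        assert fc[fc["dose"] > 0]["log2fc"].iloc[0] == pytest.approx(1.0)

    def test_missing_control_is_an_error_naming_the_key(self):
        tensor = make_tensor({("drug", 1.0): [8, 8, 8, 8]})
        with pytest.raises(ValueError, match="ab1"):
            collapse_log2fc(tensor)

    def test_nonpositive_values_rejected(self):
        tensor = make_tensor({("DMSO", 0.0): [8, 8, -1, 8],
                              ("drug", 1.0): [8, 8, 8, 8]})
        with pytest.raises(ValueError):
            collapse_log2fc(tensor)

    def test_zero_noise_recovers_planted_log2_signal(self):
        cfg = simulate.SimConfig(n_cell_lines=1, drugs=("dA", "dB"),
                                 n_signals=5, n_latent=2, noise_sd=0.0,
                                 seed=9)
        tensor, truth = simulate.generate_rppa(cfg)
        fc = collapse_log2fc(tensor[tensor["scanner"] == "A"])
        design = assemble_design(fc, signals=list(cfg.signals),
                                 times=list(cfg.times_signal),
                                 drugs=list(cfg.drugs))
        recovered = design.unscale()
        expected = truth.noiseless_log2(cfg.cell_lines[0])
        np.testing.assert_allclose(recovered.to_numpy(),
                                   expected.to_numpy(), atol=1e-9)


class TestAssembleDesign:
    def test_default_dense_design_is_35_by_105(self, default_study):
        assert default_study["design"].shape == (35, 105)

    def test_columns_are_zero_mean_unit_sd(self, default_study):
        vals = default_study["design"].values
        np.testing.assert_allclose(vals.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(vals.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_rows_ordered_drug_then_descending_dose(self, default_study):
        idx = default_study["design"].values.index
        cfg = default_study["cfg"]
        assert list(idx.get_level_values("drug").unique()) == list(cfg.drugs)
        doses = idx.get_level_values("dose")[:cfg.n_doses]
        assert (np.diff(doses) < 0).all()

    def test_zero_variance_column_flagged_and_zeroed(self):
        rows = []
        for drug, dose in [("d", 1.0), ("d", 0.5), ("d", 0.25), ("d", 0.1)]:
            rows.append(("CL", drug, dose, 1.0, "flat", 0.7))
            rows.append(("CL", drug, dose, 1.0, "varies", np.log2(dose)))
        fc = pd.DataFrame(rows, columns=["cell_line", "drug", "dose",
                                         "time", "antibody", "log2fc"])
        design = assemble_design(fc)
        assert design.zero_variance[("flat", 1.0)]
        assert (design.values[("flat", 1.0)] == 0).all()
        assert not design.zero_variance[("varies", 1.0)]

    def test_unscale_round_trips_fold_changes(self, default_study):
        fc = default_study["fc"]
        cfg = default_study["cfg"]
        design = default_study["design"]
        back = design.unscale()
        pivot = (fc[(fc["cell_line"] == cfg.cell_lines[0])
                    & (fc["dose"] > 0)]
                 .pivot_table(index=["drug", "dose"],
                              columns=["antibody", "time"], values="log2fc")
                 .reindex(index=back.index)
                 .reindex(columns=back.columns))
        np.testing.assert_allclose(back.to_numpy(), pivot.to_numpy(),
                                   atol=1e-12)

    def test_missing_cells_error_unless_imputed(self):
        rows = [("CL", "d", 1.0, 1.0, "ab", 0.5),
                ("CL", "d", 0.5, 1.0, "ab", 0.2),
                ("CL", "d", 1.0, 2.0, "ab", 0.1)]
        fc = pd.DataFrame(rows, columns=["cell_line", "drug", "dose",
                                         "time", "antibody", "log2fc"])
        with pytest.raises(ValueError, match="missing"):
            assemble_design(fc)
        design = assemble_design(fc, impute=True)
        assert not design.values.isna().any().any()

    def test_nine_dose_design_has_matching_rows(self):
        cfg = simulate.SimConfig(n_cell_lines=1, drugs=("dA", "dB"),
                                 n_signals=3, n_doses=9, dilution_ratio=2.5,
                                 seed=10)
        _, _, _, design, _, _, _ = run_signal_pipeline(cfg)
        assert design.shape == (2 * 9, 3 * 5)


class TestConsistencyMask:
    def test_identical_tables_keep_everything(self, default_study):
        fc = default_study["fc"]
        mask, frac = consistency_mask(fc, fc.copy())
        assert frac == 1.0
        assert mask.all()

    def test_sign_flip_removes_everything(self, default_study):
        fc = default_study["fc"]
        flipped = fc.copy()
        flipped["log2fc"] = -flipped["log2fc"]
        mask, frac = consistency_mask(fc, flipped)
        assert frac == 0.0

    def test_small_noise_keeps_nearly_all_strong_variables(self):
        # variable means ~N(+-1, .) with per-entry noise sd 0.05 over 35
        # conditions: sign-flip probability of a mean is ~0
        rng = np.random.default_rng(12)
        conds = [("d", float(d), 1.0) for d in range(1, 36)]
        signs = rng.choice([-1.0, 1.0], size=105)
        rows_a, rows_b = [], []
        for k in range(105):
            mu = signs[k] * rng.uniform(0.5, 1.5)
            for drug, dose, t in conds:
                base = mu + rng.normal(0, 0.2)
                rows_a.append(("CL", drug, dose, t, f"v{k}", base))
                rows_b.append(("CL", drug, dose, t, f"v{k}",
                               base + rng.normal(0, 0.05)))
        cols = ["cell_line", "drug", "dose", "time", "antibody", "log2fc"]
        mask, frac = consistency_mask(pd.DataFrame(rows_a, columns=cols),
                                      pd.DataFrame(rows_b, columns=cols))
        assert frac >= 0.95

    def test_variable_mismatch_rejected(self, default_study):
        fc = default_study["fc"]
        with pytest.raises(ValueError):
            consistency_mask(fc, fc[fc["antibody"] != "pS6"])


def test_qc_commutes_with_cell_line_restriction():
    """Filters applied to a two-line tensor agree with per-line application."""
    cfg = simulate.SimConfig(n_cell_lines=2, drugs=("dA",), n_signals=4,
                             seed=13)
    tensor, _ = simulate.generate_rppa(cfg)
    a = tensor[tensor["scanner"] == "A"]
    fc_joint = collapse_log2fc(a)
    for cl in cfg.cell_lines:
        fc_single = collapse_log2fc(a[a["cell_line"] == cl])
        joint_part = (fc_joint[fc_joint["cell_line"] == cl]
                      .sort_values(["drug", "dose", "time", "antibody"])
                      .reset_index(drop=True))
        single = (fc_single
                  .sort_values(["drug", "dose", "time", "antibody"])
                  .reset_index(drop=True))
        pd.testing.assert_frame_equal(joint_part, single)
        retained_joint, _ = antibody_qc(tensor, cl)
        retained_single, _ = antibody_qc(
            tensor[tensor["cell_line"] == cl], cl)
        assert retained_joint == retained_single
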