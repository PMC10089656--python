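import math

import numpy as np
import pandas as pd
import pytest

from vfcsf.crf import CRFSpec
from vfcsf.csf import CSFParamSet, extract_attributes
from vfcsf.fitting import (
    FIXED_CELLS,
    FitOptions,
    LocationCell,
    bic_value,
    build_tying,
    compare_models,
    fit_model,
    full_tying,
    negative_log_likelihood,
)
from vfcsf.observer import ExperimentDesign, make_observer, simulate_experiment


def _trials_df(cell, f, c, y):
    n = len(c)
    return pd.DataFrame(
        {
            "angle": cell.angle,
            "ecc": cell.ecc,
            "scaled": int(cell.scaled),
            "sf_cpd": f,
            "log10_contrast": c,
            "response": y,
        },
        index=range(n),
    )


CELL = LocationCell("HM", 2.0)


class TestBuildTying:
    @pytest.mark.parametrize(
        "flags,k,groups",
        [
            ((True, True, True), 24, 6),
            ((True, True, False), 16, 4),
            ((True, False, True), 16, 4),
            ((False, True, True), 12, 3),
            ((True, False, False), 8, 2),
            ((False, False, False), 4, 1),
        ],
    )
    def test_table_counts_four_param_form(self, flags, k, groups):
        spec = build_tying(*flags, csf_model="DoG")
        assert spec.k == k
        assert spec.n_groups == groups

    def test_three_param_form_counts(self):
        assert build_tying(True, True, True, "LP").k == 18
        assert build_tying(False, False, False, "LP").k == 3

    def test_tying_merges_follow_flags(self):
        spec = build_tying(True, False, True, "LP")
        part = spec.partition
        # HVA off: HM ties to LVM at each eccentricity
        for ecc in (2.0, 6.0):
            assert part[LocationCell("HM", ecc)] == part[LocationCell("LVM", ecc)]
            assert part[LocationCell("UVM", ecc)] != part[LocationCell("LVM", ecc)]
        spec = build_tying(True, True, False, "LP")
        for ecc in (2.0, 6.0):
            assert spec.partition[LocationCell("UVM", ecc)] == spec.partition[
                LocationCell("LVM", ecc)
            ]

    def test_scaled_cells_get_own_groups(self):
        from vfcsf.fitting import SCALED_CELLS

        spec = build_tying(False, False, False, "LP", cells=FIXED_CELLS + SCALED_CELLS)
        fixed_groups = {spec.partition[c] for c in FIXED_CELLS}
        scaled_groups = {spec.partition[c] for c in SCALED_CELLS}
        assert len(fixed_groups) == 1
        assert len(scaled_groups) == 3
        assert not fixed_groups & scaled_groups


class TestNegativeLogLikelihood:
    def setup_method(self):
        self.params = CSFParamSet("LP", alpha=2.0, beta=1.5, delta=100.0)
        self.partition = {CELL: 0}
        self.crf = CRFSpec()

    def test_single_correct_trial_at_threshold(self):
        # p = 0.75 at c = ct -> nll = -ln 0.75
        ct = -math.log10(100.0 * math.exp(-((math.log2(4.0 / 2.0) / 1.5) ** 2)))
        trials = _trials_df(CELL, [4.0], [ct], [1])
        nll = negative_log_likelihood(trials, {0: self.params}, self.partition, self.crf)
        assert nll == pytest.approx(-math.log(0.75), abs=1e-9)

    def test_saturating_contrast_upper_asymptote(self):
        trials = _trials_df(CELL, [2.0] * 10, [10.0] * 10, [1] * 10)
        nll = negative_log_likelihood(trials, {0: self.params}, self.partition, self.crf)
        assert nll == pytest.approx(-10 * math.log(0.99), rel=1e-6)

    def test_additivity_over_concatenation(self):
        t1 = _trials_df(CELL, [1.0, 2.0], [-1.0, -1.5], [1, 0])
        t2 = _trials_df(CELL, [4.0, 8.0], [-0.5, -2.0], [0, 1])
        both = pd.concat([t1, t2], ignore_index=True)
        args = ({0: self.params}, self.partition, self.crf)
        assert negative_log_likelihood(both, *args) == pytest.approx(
            negative_log_likelihood(t1, *args) + negative_log_likelihood(t2, *args)
        )

    def test_shuffle_invariance(self, rng):
        c = rng.uniform(-2, 0, 200)
        f = rng.choice([0.5, 2.0, 8.0], 200)
        y = rng.integers(0, 2, 200)
        trials = _trials_df(CELL, f, c, y)
        args = ({0: self.params}, self.partition, self.crf)
        a = negative_log_likelihood(trials, *args)
        b = negative_log_likelihood(trials.sample(frac=1, random_state=0), *args)
        assert a == pytest.approx(b, abs=1e-12)

    def test_unknown_cell_error_lists_known(self):
        trials = _trials_df(LocationCell("UVM", 6.0), [1.0], [-1.0], [1])
        with pytest.raises(ValueError, match="HM_2"):
            negative_log_likelihood(trials, {0: self.params}, self.partition, self.crf)


class TestBIC:
    def test_hand_value(self):
        assert bic_value(2, 100, -50.0) == pytest.approx(2 * math.log(100) + 100)

    def test_zero_parameters(self):
        assert bic_value(0, 50, -12.0) == pytest.approx(24.0)

    def test_equal_loglik_delta_is_dk_ln_n(self):
        n, ll = 500, -200.0
        assert bic_value(10, n, ll) - bic_value(4, n, ll) == pytest.approx(6 * math.log(n))


class TestFitModel:
    def test_nested_models_likelihood_ordering(self, small_fit):
        fixed, full = small_fit
        restricted = fit_model(
            fixed, "LP", build_tying(True, False, False, "LP"),
            opts=FitOptions(n_starts=6, seed=0),
        )
        assert full.loglik >= restricted.loglik - 1e-6

    def test_tying_identity_under_no_hva(self, small_fit):
        fixed, _ = small_fit
        fit = fit_model(
            fixed, "LP", build_tying(True, False, True, "LP"),
            opts=FitOptions(n_starts=4, seed=1),
        )
        hm = fit.params_for_cell(LocationCell("HM", 2.0))
        lvm = fit.params_for_cell(LocationCell("LVM", 2.0))
        assert hm is lvm  # bit-identical parameter object

    def test_deterministic_under_seed(self, small_fit):
        fixed, _ = small_fit
        opts = FitOptions(n_starts=3, seed=42)
        spec = build_tying(False, False, False, "LP")
        a = fit_model(fixed, "LP", spec, opts=opts)
        b = fit_model(fixed, "LP", spec, opts=opts)
        assert a.params_by_group == b.params_by_group
        assert a.bic == b.bic

    def test_k_and_bic_consistency(self, small_fit):
        _, fit = small_fit
        assert fit.k == fit.vf_spec.k == 18
        assert fit.bic == pytest.approx(bic_value(fit.k, fit.n, fit.loglik))

    def test_empty_group_rejected(self, small_fit):
        fixed, _ = small_fit
        only_2deg = fixed[fixed["ecc"] == 2.0]
        with pytest.raises(ValueError, match="no trials"):
            fit_model(only_2deg, "LP", build_tying(True, True, True, "LP"))

    def test_parameter_recovery(self):
        """Peak-CS recovered within 15% of truth in >= 90% of seeded replicates."""
        truth = CSFParamSet("LP", alpha=2.0, beta=2.2, delta=80.0)
        cell = LocationCell("LVM", 2.0)
        spec = full_tying("LP", (cell,))
        ok = 0
        n_rep = 25
        for seed in range(n_rep):
            obs = make_observer(observer_id="o", base=truth)
            from vfcsf.titration import run_titration

            rows = []
            rng_root = np.random.SeedSequence(seed)
            for f, ss in zip((0.5, 1, 2, 4, 8, 11.3), rng_root.spawn(6)):
                res = run_titration(obs.true_ct(cell, f), "best_pest", 50, np.random.default_rng(ss))
                rows.append(_trials_df(cell, [f] * 50, res.contrasts, res.responses))
            trials = pd.concat(rows, ignore_index=True)
            fit = fit_model(trials, "LP", spec, opts=FitOptions(n_starts=5, seed=seed))
            peak = extract_attributes(fit.params_by_group[0]).peak_cs
            ok += abs(peak - 80.0) / 80.0 < 0.15
        assert ok >= 0.9 * n_rep

    def test_recovery_degrades_with_fewer_trials(self):
        """Median recovery error at 20 trials/SF >= error at 84 trials/SF."""
        truth = CSFParamSet("LP", alpha=2.0, beta=2.2, delta=80.0)
        cell = LocationCell("LVM", 2.0)
        spec = full_tying("LP", (cell,))
        obs = make_observer(observer_id="o", base=truth)
        from vfcsf.titration import run_titration

        def median_err(n_trials):
            errs = []
            for seed in range(8):
                rows = []
                for f, ss in zip((0.5, 1, 2, 4, 8, 11.3), np.random.SeedSequence(seed).spawn(6)):
                    res = run_titration(
                        obs.true_ct(cell, f), "best_pest", n_trials, np.random.default_rng(ss)
                    )
                    rows.append(_trials_df(cell, [f] * n_trials, res.contrasts, res.responses))
                trials = pd.concat(rows, ignore_index=True)
                fit = fit_model(trials, "LP", spec, opts=FitOptions(n_starts=4, seed=seed))
                peak = extract_attributes(fit.params_by_group[0]).peak_cs
                errs.append(abs(peak - 80.0))
            return np.median(errs)

        assert median_err(20) >= median_err(84) - 1e-9


class TestCompareModels:
    def test_single_fit_delta_zero(self, small_fit):
        _, fit = small_fit
        table = compare_models([fit])
        assert table["delta_bic"].iloc[0] == 0.0

    def test_delta_is_subtraction_and_order_invariant(self, small_fit):
        fixed, full = small_fit
        opts = FitOptions(n_starts=4, seed=0)
        fits = [
            full,
            fit_model(fixed, "LP", build_tying(True, False, False, "LP"), opts=opts),
            fit_model(fixed, "LP", build_tying(False, False, False, "LP"), opts=opts),
        ]
        t1 = compare_models(fits)
        t2 = compare_models(fits[::-1])
        assert list(t1["vf_model"]) == list(t2["vf_model"])
        np.testing.assert_allclose(
            t1["delta_bic"], t1["bic"] - t1["bic"].min(), atol=1e-12
        )

    def test_mixed_trial_sets_rejected(self, small_fit, paperlike_trials):
        fixed, fit_a = small_fit
        _, trials = paperlike_trials
        other = fit_model(
            trials, "LP", full_tying("LP", tuple({c for c in fit_a.vf_spec.partition} | set(
                __import__("vfcsf.fitting", fromlist=["SCALED_CELLS"]).SCALED_CELLS))),
            opts=FitOptions(n_starts=2, seed=0),
        )
        with pytest.raises(ValueError, match="different trial sets"):
            compare_models([fit_a, other])

    def test_model_selection_simulation(self):
        """Data with HM == LVM: -HVA tying beats the full model by BIC."""
        wins = 0
        n_rep = 8
        for seed in range(n_rep):
            obs = make_observer(ecc_drop=0.5, hva_pct=0.0, vma_pct=15.0, include_scaled=False)
            design = ExperimentDesign.small(trials_per_sf=100, seed=seed, include_mscale=False)
            trials = simulate_experiment(obs, design)
            opts = FitOptions(n_starts=4, seed=seed)
            full = fit_model(trials, "LP", build_tying(True, True, True, "LP"), opts=opts)
            nohva = fit_model(trials, "LP", build_tying(True, False, True, "LP"), opts=opts)
            wins += nohva.bic < full.bic
        assert wins >= 0.8 * n_rep
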