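"""Truth generation, curve simulation, and parameter-recovery calibration."""

import numpy as np
import pandas as pd
import pytest

from nachr_pharm import (
    CORE_PANEL_RECEPTORS,
    DesignSpec,
    FitConfig,
    NoiseConfig,
    TruthConfig,
    fit_factor_model,
    fit_panel,
    generate_truth,
    parse_subunit_set,
    recovery_experiment,
    simulate_curves,
)
from nachr_pharm.synthetic import curve_grid, shared_median_grid


FAST_FIT = FitConfig(grid_step=1.0)  # coarser multistart; ample for clean curves


class TestGenerateTruth:
    def test_zero_effects_flat_surface(self):
        cfg = TruthConfig(
            subunit_effects={s: 0.0 for s in ("Da1", "Da2", "Da3", "Db2", "Db1")},
            intercept=6.0,
        )
        truth = generate_truth(cfg)
        neon = truth.frame[truth.frame["ligand"] == "ACh"]
        assert (neon["pec50_mean"] == 6.0).all()

    def test_additive_arithmetic(self):
        truth = generate_truth(TruthConfig())
        val = truth.pec50("Da3/Db1", "ACh")
        assert val == pytest.approx(6.96 + 0.524, abs=1e-12)

    def test_refit_recovers_configured_coefficients(self):
        cfg = TruthConfig()
        truth = generate_truth(cfg)
        fit = fit_factor_model(truth, DesignSpec("pec50"))
        for s in ("Da1", "Da2", "Da3", "Db2"):
            assert fit.coef(s) == pytest.approx(cfg.subunit_effects[s], abs=1e-10)
        assert fit.coef("intercept") == pytest.approx(cfg.intercept, abs=1e-10)
        for lig, off in cfg.compound_offsets.items():
            assert fit.coef(lig) == pytest.approx(off, abs=1e-10)

    def test_unconfigured_subunit_rejected(self):
        cfg = TruthConfig(
            subunit_effects={"Da1": 0.0, "Db1": 0.0},
            receptors=(parse_subunit_set("Da1/Da2/Db1"),),
        )
        with pytest.raises(ValueError, match="Da2"):
            generate_truth(cfg)

    def test_nonfunctional_receptor_rejected(self):
        with pytest.raises(ValueError, match="Db1"):
            TruthConfig(receptors=(parse_subunit_set("Da1/Da2"),))

    def test_reference_invariants_enforced(self):
        with pytest.raises(ValueError):
            TruthConfig(compound_imax={"ACh": 0.9})


class TestSimulateCurves:
    def test_zero_noise_on_curve(self):
        truth = generate_truth(TruthConfig(seed=2))
        rec = simulate_curves(truth, NoiseConfig(response_sigma=0.0, seed=2))
        from nachr_pharm.hill import hill_response
        row = truth.frame.iloc[0]
        sub = rec[(rec["receptor"] == row["receptor"].canonical)
                  & (rec["ligand"] == row["ligand"])
                  & (rec["oocyte_id"].str.endswith("oo1"))]
        expect = hill_response(sub["concentration_molar"].to_numpy(),
                               row["pec50_mean"], row["imax_mean"], row["nh"])
        assert np.allclose(sub["response"].to_numpy(), expect, atol=1e-15)

    def test_seed_determinism(self):
        truth = generate_truth(TruthConfig(seed=5))
        a = simulate_curves(truth, NoiseConfig(seed=9))
        b = simulate_curves(truth, NoiseConfig(seed=9))
        pd.testing.assert_frame_equal(a, b)
        c = simulate_curves(truth, NoiseConfig(seed=10))
        assert not a["response"].equals(c["response"])

    def test_default_grid_brackets_each_curve(self):
        grid = curve_grid(7.25)
        assert len(grid) == 8
        assert np.allclose(np.diff(np.log10(grid)), 0.5)
        assert np.log10(grid).mean() == pytest.approx(-7.25, abs=1e-12)
        truth = generate_truth(TruthConfig())
        shared = shared_median_grid(truth)
        med = np.median(truth.frame["pec50_mean"])
        assert np.log10(shared).mean() == pytest.approx(-med, abs=1e-9)

    def test_responses_truncated_at_zero(self):
        truth = generate_truth(TruthConfig(seed=1))
        rec = simulate_curves(truth, NoiseConfig(response_sigma=0.5, seed=1))
        assert (rec["response"] >= 0).all()

    def test_replicate_count(self):
        truth = generate_truth(TruthConfig(seed=0))
        rec = simulate_curves(truth, NoiseConfig(n_oocytes=3, seed=0))
        assert len(rec) == 48 * 3 * 8


class TestEndToEnd:
    def test_zero_noise_identifiability(self):
        # simulate -> Hill fit -> factor model recovers configured truth
        cfg = TruthConfig(seed=3)
        truth = generate_truth(cfg)
        rec = simulate_curves(truth, NoiseConfig(response_sigma=0.0, seed=3))
        fitted = fit_panel(rec, FAST_FIT)
        lm = fit_factor_model(fitted, DesignSpec("pec50"))
        for s in ("Da1", "Da2", "Da3", "Db2"):
            assert lm.coef(s) == pytest.approx(cfg.subunit_effects[s], abs=1e-4)
        assert lm.coef("intercept") == pytest.approx(cfg.intercept, abs=1e-4)

    def test_recovery_report_zero_noise(self):
        rep = recovery_experiment(
            TruthConfig(seed=4), NoiseConfig(response_sigma=0.0, seed=4), n_reps=1)
        for s, stats in rep["subunits"].items():
            assert abs(stats["bias"]) < 1e-4
            assert stats["rmse"] < 1e-4
        assert abs(rep["hill_pec50"]["bias"]) < 1e-6

    def test_recovery_calibration(self):
        # sigma 0.03, 5 oocytes, 100 replicates: nominal 95% CIs on the four
        # subunit effects cover truth within [90%, 99%], and the Hill stage
        # recovers pEC50 with |bias| < 0.05 for every ligand whose true
        # efficacy clears the noise floor.  Thiacloprid (true Imax 0.049,
        # barely 1.6x the response noise) is excluded: a response that small
        # is not reliably measurable under additive noise, and its pEC50
        # errors are heavy-tailed by construction.
        rep = recovery_experiment(
            TruthConfig(seed=0), NoiseConfig(response_sigma=0.03, seed=100),
            n_reps=100)
        for s, stats in rep["subunits"].items():
            assert 0.90 <= stats["ci_coverage"] <= 0.99, (s, stats)
            assert abs(stats["bias"]) < 0.05, (s, stats)
        for lig, stats in rep["hill_pec50_by_ligand"].items():
            if stats["true_imax"] >= 0.1:
                assert abs(stats["bias"]) < 0.05, (lig, stats)

    def test_noise_monotonicity_of_rmse(self):
        # doubling sigma must not reduce any parameter's RMSE (40 replicates
        # on a reduced 6-receptor panel keeps this check quick).  Only
        # ligands with efficacy above the noise floor are simulated: at
        # sigma 0.06 a 0.049-amplitude curve is indistinguishable from
        # noise and its "fit" is meaningless.
        receptors = tuple(parse_subunit_set(s) for s in (
            "Da1/Db1", "Da3/Db1", "Da1/Da2/Db1",
            "Da2/Da3/Db1/Db2", "Da1/Da3/Db1/Db2", "Da1/Da2/Da3/Db1",
        ))
        tcfg = TruthConfig(
            receptors=receptors, seed=6,
            compound_offsets={"imidacloprid": 1.414, "clothianidin": 2.229},
            compound_imax={"ACh": 1.0, "imidacloprid": 0.119,
                           "clothianidin": 0.667},
        )
        lo = recovery_experiment(tcfg, NoiseConfig(0.03, seed=50), n_reps=40,
                                 fit_config=FAST_FIT)
        hi = recovery_experiment(tcfg, NoiseConfig(0.06, seed=50), n_reps=40,
                                 fit_config=FAST_FIT)
        for s in lo["subunits"]:
            assert hi["subunits"][s]["rmse"] >= lo["subunits"][s]["rmse"]
        assert hi["hill_pec50"]["rmse"] >= lo["hill_pec50"]["rmse"]
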