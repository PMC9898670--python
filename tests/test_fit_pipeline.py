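"""Ensemble filtering and the end-to-end pipeline."""

import json

import numpy as np
import pytest

from helixfit import sequence_tools as st
from helixfit import scattering as sc
from helixfit.helix_builder import principal_axis
from helixfit.ensemble_generator import (ConformerEnsemble, SamplerParams,
                                         bend_angle, generate_conformers,
                                         _apply_hinge, _perpendicular_axis)
from helixfit.fit_pipeline import FitConfig, filter_ensemble, load_config, \
    run_pipeline
from helixfit.synthetic_data import NoiseParams, make_synthetic_curves


@pytest.fixture(scope="module")
def mass(pog10_chain):
    return st.trimer_mass(pog10_chain)


@pytest.fixture(scope="module")
def small_ensemble(pog10_model):
    return generate_conformers(pog10_model, 80,
                               SamplerParams(5, 90.0, 0.0), seed=21)


def bent_truth(model, angle, azimuth=0.7):
    axis = _perpendicular_axis(principal_axis(model), azimuth)
    return _apply_hinge(model, 5, angle, axis, principal_axis(model))


class TestFilterEnsemble:
    def test_exact_generating_model_ranks_first(self, pog10_model, mass,
                                                small_ensemble):
        truth = small_ensemble.conformers[17]
        exp = make_synthetic_curves(truth, mass,
                                    noise=NoiseParams(sigma_rel=0.0), seed=0)
        res = filter_ensemble(small_ensemble, mass, exp.curves["hydrated"])
        assert res.ranked[0] == 17
        # the fitted scale factor is resolved to ~1e-6, which bounds R
        assert res.best.r_factor_xray < 1e-3

    def test_linear_scores_worse_than_best_on_bent_target(self, pog10_model,
                                                          mass,
                                                          small_ensemble):
        truth = bent_truth(pog10_model, 40.0)
        exp = make_synthetic_curves(truth, mass,
                                    noise=NoiseParams(sigma_rel=0.02), seed=3)
        res = filter_ensemble(small_ensemble, mass, exp.curves["hydrated"])
        lin_hyd = sc.add_hydration(sc.coarse_grain(pog10_model), mass)
        lin_curve = sc.debye_curve(lin_hyd, exp.curves["hydrated"].q)
        lin_r = sc.r_factor(exp.curves["hydrated"], lin_curve).r_factor
        assert res.best.r_factor_xray < lin_r

    def test_adding_conformers_never_worsens_best(self, pog10_model, mass):
        truth = bent_truth(pog10_model, 35.0)
        exp = make_synthetic_curves(truth, mass,
                                    noise=NoiseParams(sigma_rel=0.02), seed=8)
        full = generate_conformers(pog10_model, 60,
                                   SamplerParams(5, 90.0, 0.0), seed=2)
        half = ConformerEnsemble(full.conformers[:30], full.params, full.seed,
                                 full.bends_applied[:30])
        r_half = filter_ensemble(half, mass, exp.curves["hydrated"])
        r_full = filter_ensemble(full, mass, exp.curves["hydrated"])
        assert r_full.best.r_factor_xray <= r_half.best.r_factor_xray

    def test_top10_forms_tight_bend_band_without_noise(self, pog10_model,
                                                       mass):
        truth = bent_truth(pog10_model, 45.0)
        exp = make_synthetic_curves(truth, mass,
                                    noise=NoiseParams(sigma_rel=0.0), seed=0)
        ens = generate_conformers(pog10_model, 400,
                                  SamplerParams(5, 90.0, 0.0), seed=5)
        res = filter_ensemble(ens, mass, exp.curves["hydrated"])
        bends = [r.bend for r in res.top(10)]
        assert max(bends) - min(bends) <= 15.0

    def test_xray_and_neutron_select_overlapping_top_sets(self, pog10_model,
                                                          mass,
                                                          small_ensemble):
        truth = bent_truth(pog10_model, 50.0)
        exp = make_synthetic_curves(truth, mass,
                                    noise=NoiseParams(sigma_rel=0.0), seed=4)
        res = filter_ensemble(small_ensemble, mass, exp.curves["hydrated"],
                              exp.curves["dry"])
        top_x = set(res.ranked[:10])
        by_neutron = sorted(range(len(res.records)),
                            key=lambda i: res.records[i].r_factor_neutron)
        top_n = set(by_neutron[:10])
        assert len(top_x & top_n) >= 5

    def test_contrast_mismatch_rejected(self, mass, small_ensemble):
        q = np.linspace(0.05, 2.0, 40)
        wrong = sc.ScatteringCurve(q, np.exp(-q), contrast="dry")
        with pytest.raises(ValueError, match="contrast"):
            filter_ensemble(small_ensemble, mass, wrong)


class TestRunPipeline:
    def test_demo_config_end_to_end(self, tmp_path):
        cfg = FitConfig(sequence="Ac-(POG)4-QG-(POG)5-NH2", name="demo",
                        n_conformers=60, seed=13, synthetic_truth_bend=45.0)
        report = run_pipeline(cfg, tmp_path / "out")
        assert (tmp_path / "out" / "report.json").exists()
        assert (tmp_path / "out" / "best_fit.pdb").exists()
        assert (tmp_path / "out" / "rfactor_scatter.csv").exists()
        assert report["best_fit"]["r_factor_xray"] <= \
            report["linear_model"]["r_factor_xray"] + 1e-9
        assert report["peptide"]["hinge_triplet"] == 5

    def test_rerun_is_byte_identical(self, tmp_path):
        cfg = FitConfig(sequence="Ac-(POG)10-NH2", n_conformers=40, seed=7,
                        synthetic_truth_bend=30.0)
        run_pipeline(cfg, tmp_path / "a")
        run_pipeline(cfg, tmp_path / "b")
        for name in ("report.json", "ensemble_manifest.json",
                     "rfactor_scatter.csv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_missing_curve_file_fails_before_compute(self, tmp_path):
        toml = tmp_path / "run.toml"
        toml.write_text('sequence = "Ac-(POG)10-NH2"\n'
                        'xray_curve = "does_not_exist.dat"\n')
        with pytest.raises(FileNotFoundError):
            load_config(toml)

    def test_config_requires_a_target(self, tmp_path):
        toml = tmp_path / "run.toml"
        toml.write_text('sequence = "Ac-(POG)10-NH2"\n')
        with pytest.raises(ValueError):
            load_config(toml)
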