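"""Synthetic cohort generator: layout, determinism, batch distortions and
the survival-generating mechanism."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

import cytoresponse as cr
from cytoresponse.core import ValidationError
from cytoresponse.synth import HEALTHY_COMPOSITION, simulate_patients


def test_manifest_layout_counts():
    # 32 patients x 3 timepoints + 7 references + 7 healthy donors
    spec = cr.CohortSpec(n_patients=32, n_batches=7, cells_per_sample=100, seed=0)
    coh = cr.generate_cohort(spec)
    assert len(coh.manifest) == 32 * 3 + 7 + 7 == 110
    roles = coh.manifest["sample_role"].value_counts()
    assert roles["patient"] == 96
    assert roles["batch_reference"] == 7
    assert roles["healthy_donor"] == 7
    assert len(coh.clinical) == 32
    # every emitted table is referenced by the manifest and non-negative
    for sid in coh.manifest["sample_id"]:
        assert (coh.samples[sid].data.to_numpy() >= 0).all()


def test_seeded_determinism_byte_identical(small_spec):
    a = cr.generate_cohort(small_spec)
    b = cr.generate_cohort(small_spec)
    assert a.manifest.to_csv() == b.manifest.to_csv()
    assert a.clinical.to_csv() == b.clinical.to_csv()
    for sid in a.samples:
        assert a.samples[sid].data.to_csv() == b.samples[sid].data.to_csv()
        assert (a.truth.cell_labels[sid] == b.truth.cell_labels[sid]).all()


def test_composition_matches_cell_counts(small_cohort):
    truth = small_cohort.truth
    for sid, labels in truth.cell_labels.items():
        counts = pd.Series(labels).value_counts(normalize=True)
        assert abs(counts.sum() - 1.0) < 1e-12


def test_healthy_donor_composition():
    spec = cr.CohortSpec(n_patients=1, n_batches=7, cells_per_sample=2000, seed=3)
    coh = cr.generate_cohort(spec)
    fracs = []
    for t in coh.tables(role="healthy_donor"):
        labels = pd.Series(coh.truth.cell_labels[t.sample_id])
        f = labels.value_counts(normalize=True)
        fracs.append(f)
    mean = pd.concat(fracs, axis=1).fillna(0).mean(axis=1)
    lymphoid = mean.get("t_cd4", 0) + mean.get("t_cd8", 0) + mean.get("b_cells", 0) + mean.get("nk_cells", 0)
    assert abs(mean["granulocytes"] - 0.60) < 0.05
    assert abs(lymphoid - 0.30) < 0.05
    assert abs(mean["monocytes"] - 0.03) < 0.05


def test_invalid_specs_name_the_field():
    with pytest.raises(ValidationError, match="cells_per_sample"):
        cr.CohortSpec(cells_per_sample=50).validate()
    with pytest.raises(ValidationError, match="timepoints"):
        cr.CohortSpec(timepoints=(0.0, 4.0)).validate()
    with pytest.raises(ValidationError, match="is_target"):
        pops = tuple(
            cr.PopulationTemplate(p.name, p.surface_means, is_target=False)
            for p in cr.CohortSpec().populations
        )
        cr.CohortSpec(populations=pops).validate()
    with pytest.raises(ValidationError, match="slope"):
        cr.CohortSpec(batch_slope_range=(-0.1, 1.0)).validate()


class TestApplyBatchEffect:
    def test_identity(self, small_cohort):
        t = next(iter(small_cohort.samples.values()))
        params = {ch: (1.0, 0.0) for ch in t.channels}
        out = cr.apply_batch_effect(t, params)
        np.testing.assert_allclose(out.data.to_numpy(), t.data.to_numpy(), rtol=1e-12)

    def test_offset_exact_on_transformed_scale(self, small_cohort):
        t = next(iter(small_cohort.samples.values()))
        ch = t.channels[0]
        out = cr.apply_batch_effect(t, {ch: (1.0, 0.3)}, cofactor=5.0)
        v_in = np.arcsinh(t.data[ch].to_numpy() / 5.0)
        v_out = np.arcsinh(out.data[ch].to_numpy() / 5.0)
        np.testing.assert_allclose(v_out, v_in + 0.3, atol=1e-12)

    def test_quantile_equivariance_under_affine(self):
        # 101 empirical quantiles of the distorted aliquot equal a*q + b of
        # the undistorted quantiles on the transformed scale
        spec = cr.CohortSpec(n_patients=1, n_batches=2, cells_per_sample=5000, seed=5)
        coh = cr.generate_cohort(spec)
        ref = coh.references()["B1"]
        a_b = coh.truth.batch_params["B1"]
        grid = np.linspace(0, 1, 101)
        for ch in ref.channels[:8]:
            a, b = a_b[ch]
            v = np.arcsinh(ref.data[ch].to_numpy() / 5.0)
            q0 = np.quantile((v - b) / a, grid)  # undistorted transformed values
            q1 = np.quantile(v, grid)
            np.testing.assert_allclose(q1, a * q0 + b, atol=1e-9)

    def test_rank_preserved_and_slope_validated(self, small_cohort):
        t = next(iter(small_cohort.samples.values()))
        ch = t.channels[0]
        out = cr.apply_batch_effect(t, {ch: (1.3, 0.2)})
        assert (
            np.argsort(out.data[ch].to_numpy(), kind="stable")
            == np.argsort(t.data[ch].to_numpy(), kind="stable")
        ).all()
        with pytest.raises(ValidationError, match="slope"):
            cr.apply_batch_effect(t, {ch: (0.0, 0.1)})


class TestSimulateSurvival:
    def test_beta_zero_independence(self):
        rng = np.random.default_rng(0)
        latent = rng.normal(size=1000)
        surv = cr.simulate_survival(latent, cr.SurvivalModel(beta=0.0), seed=1)
        r = np.corrcoef(latent, surv["event_time"])[0, 1]
        assert abs(r) < 0.07

    def test_zero_horizon_censors_everything_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            surv = cr.simulate_survival(
                np.zeros(10) + np.arange(10),
                cr.SurvivalModel(censor_horizon_days=0.0),
                seed=0,
            )
        assert (surv["os_days"] == 0).all()
        assert (surv["os_event"] == 0).all()

    def test_stronger_beta_shortens_high_risk_survival(self):
        rng = np.random.default_rng(2)
        latent = rng.normal(size=1000)
        top = latent >= np.quantile(latent, 0.75)
        means = {}
        for beta in (1.0, 2.0):
            surv = cr.simulate_survival(latent, cr.SurvivalModel(beta=beta), seed=7)
            means[beta] = surv.loc[top, "event_time"].mean()
        assert means[2.0] < means[1.0]

    def test_validation(self):
        with pytest.raises(ValidationError, match="baseline_hazard"):
            cr.simulate_survival(np.ones(3), cr.SurvivalModel(baseline_hazard=0.0))
        with pytest.raises(ValidationError, match="finite"):
            cr.simulate_survival(np.array([1.0, np.nan]), cr.SurvivalModel())


def test_proportional_hazards_recovery():
    # univariate Cox on the true standardized latent recovers beta
    spec = cr.CohortSpec(n_patients=1000, cells_per_sample=100, seed=9)
    pats = simulate_patients(spec)
    surv = cr.simulate_survival(pats["latent_p90_24h"].to_numpy(), spec.survival, seed=4)
    df = pd.DataFrame({"z": surv["z"], "time": surv["os_days"], "event": surv["os_event"]})
    cph = CoxPHFitter().fit(df, duration_col="time", event_col="event")
    assert abs(cph.params_["z"] - spec.survival.beta) < 0.15


def test_reference_aliquots_share_distribution_before_distortion():
    spec = cr.CohortSpec(
        n_patients=1, n_batches=3, cells_per_sample=100, reference_cells=10000, seed=13
    )
    coh = cr.generate_cohort(spec)
    from scipy.stats import ks_2samp

    refs = coh.references()

    def undistorted(b, ch):
        # invert the affine distortion analytically on the transformed scale;
        # round so the zero-floor atom lands on one side of 0 in both batches
        a, off = coh.truth.batch_params[b][ch]
        return np.round((np.arcsinh(refs[b].data[ch].to_numpy() / 5.0) - off) / a, 9)

    pre_max = 0.0
    for ch in spec.panel.all_channels:
        d_undist = ks_2samp(undistorted("B1", ch), undistorted("B2", ch)).statistic
        assert d_undist < 0.03
        d_dist = ks_2samp(refs["B1"].data[ch], refs["B2"].data[ch]).statistic
        pre_max = max(pre_max, d_dist)
    assert pre_max > 0.2  # distortion is visible on at least one channel


def test_optional_missing_4h_samples():
    spec = cr.CohortSpec(n_patients=5, n_batches=2, cells_per_sample=100, n_drop_4h=2, seed=1)
    coh = cr.generate_cohort(spec)
    pm = coh.manifest[coh.manifest["sample_role"] == "patient"]
    per_patient = pm.groupby("patient_id")["timepoint_h"].apply(set)
    n_missing = sum(1 for tps in per_patient if 4.0 not in tps)
    assert n_missing == 2
    assert all({0.0, 24.0} <= tps for tps in per_patient)
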