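"""Chained sub-models: fitting, re-closure, route prediction, validation."""
import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omstab.characterize import FEATURE_NAMES, N_FEATURES, SampleRecord
from omstab.coupling import (
    CoupledModel,
    SubModelSpec,
    couple_predict,
    fit_coupled,
    fit_submodel,
    reclose_profile,
    validate_holdout,
    _subset_indices,
)
from omstab.dataset import StudyDataset, TreatmentPair, parse_family
from omstab.pls import fit_pls
from omstab.synthetic import (
    GeneratorParams,
    apply_treatment,
    generate_dataset,
    generate_wastes,
    true_cnm,
)

HOLDOUT = ("W01", "W26")


def low_rank_records(n, rank, seed=5, positive=True):
    """Records whose features live on a low-dimensional affine subspace."""
    rng = np.random.default_rng(seed)
    basis = rng.normal(size=(rank, N_FEATURES))
    mean = np.full(N_FEATURES, 20.0)
    recs, coeffs = [], []
    for i in range(n):
        z = rng.normal(size=rank)
        coeffs.append(z)
        recs.append(SampleRecord(f"S{i:02d}", mean + z @ basis))
    return recs, np.array(coeffs)


class TestFitSubmodel:
    def test_exact_linear_response_fits_perfectly(self):
        """Soil stage: C_nm an exact linear map of rank-3 features."""
        recs, _ = low_rank_records(20, 3)
        rng = np.random.default_rng(0)
        beta = rng.normal(size=N_FEATURES)
        ds = StudyDataset()
        for r in recs:
            ds.add(r, cnm=float(r.features @ beta))
        m = fit_submodel(ds, SubModelSpec("soil", n_components=3))
        assert m.r2y_cum == pytest.approx(1.0, abs=1e-6)

    def test_identity_treatment_reproduces_inputs(self):
        """AD stage with digestate == waste: per-variable R2VY ~ 1."""
        rng = np.random.default_rng(6)
        ds = StudyDataset()
        for i in range(60):
            f = rng.uniform(1, 10, N_FEATURES)
            ds.add(SampleRecord(f"I{i:02d}", f))
            ds.add(SampleRecord(f"I{i:02d}-D", f, route="AD"))
            ds.ad_pairs.append(TreatmentPair(f"I{i:02d}", f"I{i:02d}-D", 10.0 + i % 5))
        m = fit_submodel(ds, SubModelSpec("AD", n_components=34))
        # full-rank NIPALS recovers the identity to numerical convergence
        assert np.all(m.r2vy_cum > 0.97)
        # training-set self-prediction reproduces the (identical) outputs
        X_train = np.vstack(
            [np.append(ds.samples[p.input_id].features, p.duration_days)
             for p in ds.ad_pairs]
        )
        assert m.predict(X_train) == pytest.approx(X_train[:, :34], abs=1.0)

    def test_ad_stage_predictive_on_generated_study(self):
        """Treatment-shift data: AD sub-model cross-validates above 0.5."""
        ds = generate_dataset(GeneratorParams(n_wastes=60), seed=1)
        m = fit_submodel(ds, SubModelSpec("AD"))
        assert m.q2_cum >= 0.5

    def test_unpaired_sample_reported(self, default_params):
        ds = generate_dataset(default_params, seed=2)
        ds.ad_pairs.append(TreatmentPair("missing", "also-missing", 10.0))
        with pytest.raises(ValueError, match="missing"):
            fit_submodel(ds, SubModelSpec("AD"))

    def test_exclusions_and_holdout_dropped(self, study_seed1):
        m = fit_submodel(study_seed1, SubModelSpec("soil"), HOLDOUT)
        for sid in m.training_ids:
            assert parse_family(sid) not in HOLDOUT


class TestReclosure:
    def test_valid_profile_unchanged(self, default_params):
        rec = generate_wastes(default_params, seed=1)[0]
        closed, adj = reclose_profile(rec.features)
        assert closed == pytest.approx(rec.features, abs=1e-9)
        assert adj == pytest.approx(0.0, abs=1e-9)

    def test_ac_block_hand_normalization(self, default_params):
        rec = generate_wastes(default_params, seed=1)[0]
        v = rec.features.copy()
        v[1:6] = [50.0, 30.0, 10.0, 20.0, 10.0]
        closed, adj = reclose_profile(v)
        assert closed[1:6] == pytest.approx(
            [41.6667, 25.0, 8.3333, 16.6667, 8.3333], abs=1e-3
        )
        assert adj > 0

    def test_negative_entry_clipped_then_renormalized(self, default_params):
        rec = generate_wastes(default_params, seed=1)[0]
        v = rec.features.copy()
        v[6] = -2.0  # SPOM_Pf_I
        closed, _ = reclose_profile(v)
        assert closed[6] == 0.0
        assert closed[6:13].sum() == pytest.approx(100.0, abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_idempotence(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(50, 40, size=N_FEATURES)
        try:
            once, _ = reclose_profile(v)
        except ValueError:
            return  # a block collapsed to zero; rejection is the contract
        twice, adj = reclose_profile(once)
        assert twice == pytest.approx(once, abs=1e-9)
        assert adj == pytest.approx(0.0, abs=1e-9)

    def test_collapsed_block_rejected(self):
        v = np.full(N_FEATURES, 10.0)
        v[1:6] = -1.0
        with pytest.raises(ValueError, match="collapsed"):
            reclose_profile(v)


class TestCoupledPrediction:
    def test_direct_route_equals_soil_model(self, study_seed1, coupled_seed1):
        rec = study_seed1.samples["W02"]
        pred, inter = couple_predict(coupled_seed1, rec.features, "raw")
        assert inter == {}
        assert pred == pytest.approx(
            float(coupled_seed1.soil.predict(rec.features)[0, 0])
        )

    def test_missing_duration_raises(self, study_seed1, coupled_seed1):
        rec = study_seed1.samples["W02"]
        with pytest.raises(ValueError, match="duration"):
            couple_predict(coupled_seed1, rec.features, "AD")
        with pytest.raises(ValueError, match="route"):
            couple_predict(coupled_seed1, rec.features, "incineration")

    def test_identity_compost_stage_preserves_ad_route(self, study_seed1, coupled_seed1):
        """A zero-effect composting stage leaves the AD-route prediction.

        The identity stage is built directly (unit coefficient matrix, no
        duration effect), so the only possible drift is re-closure — which
        is idempotent on the already-closed intermediate profile.
        """
        from omstab.pls import PLSModel, ScalingSpec

        def unit_scaler(p):
            s = ScalingSpec(center=False, unit_variance=False)
            s.mean_ = np.zeros(p)
            s.std_ = np.ones(p)
            return s

        identity = PLSModel(
            n_components=1,
            weights=np.zeros((N_FEATURES + 1, 1)),
            x_loadings=np.zeros((N_FEATURES + 1, 1)),
            y_loadings=np.zeros((N_FEATURES, 1)),
            scores=np.zeros((0, 1)),
            coef=np.vstack([np.eye(N_FEATURES), np.zeros((1, N_FEATURES))]),
            x_scaler=unit_scaler(N_FEATURES + 1),
            y_scaler=unit_scaler(N_FEATURES),
        )
        model = CoupledModel(
            ad=coupled_seed1.ad, compost=identity, soil=coupled_seed1.soil
        )
        rec = study_seed1.samples["W02"]
        via_ad, _ = couple_predict(model, rec.features, "AD", hrt_days=40.0)
        via_both, _ = couple_predict(
            model, rec.features, "AD+compost", hrt_days=40.0, dc_days=30.0
        )
        assert via_both == pytest.approx(via_ad, abs=1e-9)

    def test_parameter_recovery_bounded_by_generator_noise(
        self, default_params, coupled_seed1
    ):
        """Chained predictions track the generator's true C_nm.

        Pooled over three fresh test batches: RMSE stays within twice the
        observation noise s.d., >= 90% of products within 2 s.d., and the
        coupled error stays within 50% of the soil sub-model's RMSEcv.
        """
        idx = _subset_indices("all")
        errs = []
        for batch_seed in (101, 202, 303):
            rng = np.random.default_rng(batch_seed)
            wastes = generate_wastes(
                dataclasses.replace(default_params, n_wastes=20), rng
            )
            for w in wastes:
                for route, hrt, dc in (
                    ("raw", None, None),
                    ("AD", 40.0, None),
                    ("compost", None, 50.0),
                    ("AD+compost", 40.0, 50.0),
                ):
                    rec = w
                    if route in ("AD", "AD+compost"):
                        rec = apply_treatment(rec, "AD", hrt, default_params, rng)
                    if route in ("compost", "AD+compost"):
                        rec = apply_treatment(rec, "compost", dc, default_params, rng)
                    obs = true_cnm(rec, default_params, rng)
                    pred, _ = couple_predict(
                        coupled_seed1, w.features[idx], route, hrt, dc
                    )
                    errs.append(pred - obs)
        errs = np.array(errs)
        rmse = float(np.sqrt((errs**2).mean()))
        assert rmse <= 2 * 2 * default_params.cnm_sigma
        assert np.mean(np.abs(errs) <= 2 * default_params.cnm_sigma) >= 0.9
        assert rmse <= 1.5 * float(coupled_seed1.soil.rmsecv[0])


class TestHoldoutValidation:
    def test_empty_holdout_gives_empty_report(self, study_seed1):
        model = fit_coupled(study_seed1)
        report = validate_holdout(study_seed1, model, ())
        assert report.rows == []
        assert np.isnan(report.rmse)

    def test_report_rows_match_family_sample_count(self, study_seed1, coupled_seed1):
        report = validate_holdout(study_seed1, coupled_seed1, HOLDOUT)
        expected = [
            sid for sid in study_seed1.samples if parse_family(sid) in HOLDOUT
        ]
        assert sorted(r["sample_id"] for r in report.rows) == sorted(expected)
        for row in report.rows:
            assert row["observed_cnm"] is None or row["abs_error"] is not None

    def test_unincubated_sample_predicted_but_unflagged(self, default_params):
        ds = generate_dataset(default_params, seed=1)
        fam = "W07"  # i = 6: raw waste carries no measured C_nm
        assert fam not in ds.cnm
        model = fit_coupled(ds, holdout_families=(fam,))
        report = validate_holdout(ds, model, (fam,))
        raw_row = next(r for r in report.rows if r["sample_id"] == fam)
        assert raw_row["observed_cnm"] is None
        assert raw_row["predicted_cnm"] is not None

    def test_leakage_detected(self, study_seed1):
        leaky = fit_coupled(study_seed1)  # trained on everything
        with pytest.raises(ValueError, match="leakage"):
            validate_holdout(study_seed1, leaky, HOLDOUT)

    def test_training_sets_disjoint_from_holdout(self, coupled_seed1):
        for sub in (coupled_seed1.ad, coupled_seed1.compost, coupled_seed1.soil):
            assert not {parse_family(s) for s in sub.training_ids} & set(HOLDOUT)


class TestAblation:
    def test_all_subset_identical_to_main_pipeline(self, study_seed1, coupled_seed1):
        from omstab.coupling import ablation_run

        reports = ablation_run(study_seed1, HOLDOUT, subsets=("all",))
        main = validate_holdout(study_seed1, coupled_seed1, HOLDOUT)
        assert reports["all"].to_frame()["predicted_cnm"].to_numpy() == pytest.approx(
            main.to_frame()["predicted_cnm"].to_numpy()
        )

    def test_accessibility_only_suffices_when_signal_is_accessible(self):
        """C_nm driven by AC variables only: the 6-variable pipeline matches
        the 34-variable one within 10% (pooled over replicates)."""
        from omstab.coupling import ablation_run

        beta = {"OM_TC": -0.3, "SPOM_AC": -1.0, "REOM_AC": -0.7, "NEOM_AC": 1.4}
        p = GeneratorParams(cnm_beta=beta)
        sq = {"all": [], "accessibility": []}
        for seed in range(1, 9):
            ds = generate_dataset(p, seed=seed)
            reports = ablation_run(ds, HOLDOUT, subsets=("all", "accessibility"))
            for k in sq:
                sq[k] += [
                    r["abs_error"] ** 2
                    for r in reports[k].rows
                    if r["abs_error"] is not None
                ]
        rmse = {k: np.sqrt(np.mean(v)) for k, v in sq.items()}
        assert rmse["accessibility"] <= 1.1 * rmse["all"]

    def test_split_signal_needs_both_blocks(self, default_params):
        """Signal in both blocks: the full model beats each single block
        (pooled over 20 replicate studies)."""
        from omstab.coupling import ablation_run

        sq = {"all": [], "accessibility": [], "complexity": []}
        for seed in range(1, 21):
            ds = generate_dataset(default_params, seed=seed)
            reports = ablation_run(ds, HOLDOUT)
            for k in sq:
                sq[k] += [
                    r["abs_error"] ** 2
                    for r in reports[k].rows
                    if r["abs_error"] is not None
                ]
        rmse = {k: np.sqrt(np.mean(v)) for k, v in sq.items()}
        assert rmse["all"] <= rmse["accessibility"]
        assert rmse["all"] <= rmse["complexity"]
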