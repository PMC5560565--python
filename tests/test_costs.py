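import numpy as np
import pytest
from scipy import ndimage

from octlayers import PhantomParams, RaterModel, generate_phantom, simulate_rater
from octlayers.volume_io import OCTVolume, downsample_volume
from octlayers.graphseg import coarse_localize, train_stage_models, build_plan
from octlayers import costs as cm

from conftest import noiseless_overrides


def _column_volume(col):
    arr = np.asarray(col, dtype=float)[None, None, :]
    return OCTVolume(arr, (1, 1, 1))


class TestGradientCost:
    def test_step_edge_minimum_at_requested_polarity(self):
        vol = _column_volume([0, 0, 0, 10, 10, 10])
        c = cm.gradient_cost(vol, "dark_to_bright", 1.0).values[0, 0]
        assert c.argmin() in (2, 3)  # the step sits between rows 2 and 3
        assert c.min() < np.median(c) - 1e-6

    def test_wrong_polarity_has_no_minimum_at_step(self):
        vol = _column_volume([0, 0, 0, 10, 10, 10])
        c = cm.gradient_cost(vol, "bright_to_dark", 1.0).values[0, 0]
        # at the step the bright-to-dark cost peaks instead
        assert c.argmax() in (2, 3)

    def test_linear_ramp_gives_constant_cost(self):
        vol = _column_volume(np.arange(32.0))
        c = cm.gradient_cost(vol, "dark_to_bright", 1.0).values[0, 0]
        interior = c[6:-6]  # away from boundary effects of the smoothing
        np.testing.assert_allclose(interior, interior[0], atol=1e-9)

    def test_translation_equivariance_along_z(self):
        # shifting the column shifts the cost profile (and its argmin) equally,
        # up to the global non-negativity offset
        rng = np.random.default_rng(0)
        base = rng.random(40)
        c1 = cm.gradient_cost(_column_volume(base), "dark_to_bright", 1.0).values[0, 0]
        c2 = cm.gradient_cost(_column_volume(np.roll(base, 7)), "dark_to_bright", 1.0).values[0, 0]
        a, b = c1[5:28], c2[12:35]
        np.testing.assert_allclose(a - a.min(), b - b.min(), atol=1e-9)

    def test_nonnegative_and_finite(self):
        rng = np.random.default_rng(1)
        c = cm.gradient_cost(_column_volume(rng.random(30)), "bright_to_dark", 2.0).values
        assert np.all(np.isfinite(c)) and c.min() >= 0

    def test_bad_arguments(self):
        vol = _column_volume([1, 2, 3])
        with pytest.raises(ValueError):
            cm.gradient_cost(vol, "dark_to_bright", 0.0)
        with pytest.raises(ValueError):
            cm.gradient_cost(vol, "sideways", 1.0)


@pytest.fixture(scope="module")
def working_setup():
    """Noiseless working-resolution volume + ROI + features."""
    params = PhantomParams(**noiseless_overrides())
    vol, truth = generate_phantom(params, seed=1)
    work = downsample_volume(vol, 2, 2)
    roi = coarse_localize(work)
    stack = cm.extract_features(work, roi)
    return work, roi, stack, truth


class TestExtractFeatures:
    def test_constant_volume_has_zero_derivative_features(self):
        vol = OCTVolume(np.full((2, 8, 64), 5.0), (1, 1, 1))

        class R:
            ilm = np.full((2, 8), 10.0)
            deep = np.full((2, 8), 50.0)
            z0, z1 = 0, 63
        stack = cm.extract_features(vol, R)
        # features 2/4/6 are the axial derivatives at the three scales
        for k in (2, 4, 6):
            np.testing.assert_allclose(stack.features[k], 0.0, atol=1e-12)

    def test_relative_depth_endpoints(self, working_setup):
        work, roi, stack, _ = working_setup
        rel = stack.features[8]
        b, x = 3, 10
        zi = int(round(roi.ilm[b, x])) - roi.z0
        zd = int(round(roi.deep[b, x])) - roi.z0
        assert rel[b, x, max(zi, 0)] < 0.02
        assert rel[b, x, min(zd, rel.shape[2] - 1)] > 0.98
        assert rel.min() >= 0 and rel.max() <= 1

    def test_impulse_response_matches_gaussian_kernel(self):
        z = np.zeros((1, 1, 65))
        z[0, 0, 32] = 1.0
        vol = OCTVolume(z, (1, 1, 1))

        class R:
            ilm = np.zeros((1, 1))
            deep = np.full((1, 1), 64.0)
            z0, z1 = 0, 64
        stack = cm.extract_features(vol, R)
        got = stack.features[1][0, 0]  # smoothed at sigma = 1
        expect = np.zeros(65)
        expect[32] = 1.0
        expect = ndimage.gaussian_filter1d(expect, 1.0)
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_empty_roi_rejected(self):
        vol = OCTVolume(np.zeros((1, 2, 8)), (1, 1, 1))

        class R:
            ilm = np.zeros((1, 2))
            deep = np.zeros((1, 2))
            z0, z1 = 5, 5
        with pytest.raises(ValueError, match="empty ROI"):
            cm.extract_features(vol, R)


@pytest.fixture(scope="module")
def trained_stage1(working_setup):
    work, roi, stack, truth = working_setup
    rater = RaterModel(sigma_um=0.0)
    delin = simulate_rater(truth, rater, [2, 6, 10, 14, 18, 22], seed=5)
    import octlayers.volume_io as vio
    scaled = vio.Delineation(
        rater=delin.rater,
        slices=[{"b": r["b"], "surface": r["surface"],
                 "points": (np.asarray(r["points"]) / 2.0).tolist()}
                for r in delin.slices],
        rule=delin.rule)
    model = cm.train_boundary_classifier(
        stack, [scaled], stage=0, stage_surfaces=("ILM", "RNFGC-IPL"),
        mode="healthy", seed=9)
    return model, stack, roi, truth


class TestBoundaryClassifier:
    def test_oob_accuracy_on_clean_phantom(self, trained_stage1):
        model, *_ = trained_stage1
        assert model.oob_accuracy > 0.9

    def test_training_is_deterministic(self, working_setup, trained_stage1):
        work, roi, stack, truth = working_setup
        model, _, _, _ = trained_stage1
        delin = simulate_rater(truth, RaterModel(sigma_um=0.0), [2, 6, 10, 14, 18, 22], seed=5)
        import octlayers.volume_io as vio
        scaled = vio.Delineation(
            rater=delin.rater,
            slices=[{"b": r["b"], "surface": r["surface"],
                     "points": (np.asarray(r["points"]) / 2.0).tolist()}
                    for r in delin.slices],
            rule=delin.rule)
        model2 = cm.train_boundary_classifier(
            stack, [scaled], stage=0, stage_surfaces=("ILM", "RNFGC-IPL"),
            mode="healthy", seed=9)
        X = stack.matrix()[:5000]
        np.testing.assert_array_equal(model.forest.predict(X), model2.forest.predict(X))

    def test_missing_surface_annotation_reported(self, working_setup):
        work, roi, stack, truth = working_setup
        delin = simulate_rater(truth, RaterModel(sigma_um=0.0), [4], seed=5)
        import octlayers.volume_io as vio
        only_ilm = vio.Delineation(
            rater="r", slices=[{"b": r["b"], "surface": r["surface"],
                                "points": (np.asarray(r["points"]) / 2.0).tolist()}
                               for r in delin.slices if r["surface"] == "ILM"])
        with pytest.raises(ValueError, match="RNFGC-IPL"):
            cm.train_boundary_classifier(stack, [only_ilm], stage=0,
                                         stage_surfaces=("ILM", "RNFGC-IPL"),
                                         mode="healthy", seed=0)

    def test_costs_are_one_minus_probability(self, trained_stage1):
        model, stack, roi, truth = trained_stage1
        cvs = cm.predict_costs(model, stack)
        assert [c.surface for c in cvs] == ["ILM", "RNFGC-IPL"]
        proba = model.forest.predict_proba(stack.matrix()[:200])
        k = list(model.forest.classes_).index(1)
        np.testing.assert_allclose(
            cvs[0].values.reshape(-1)[:200], 1.0 - proba[:, k], atol=1e-12)
        assert all(0 <= c.values.min() and c.values.max() <= 1 for c in cvs)

    def test_cost_minimum_tracks_truth_on_training_volume(self, trained_stage1):
        model, stack, roi, truth = trained_stage1
        cvs = cm.predict_costs(model, stack)
        ilm_cost = cvs[0].values
        b = 8  # held-out slice (not used in training)
        zhat = ilm_cost[b].argmin(axis=1) + stack.z0
        ztrue = truth.surfaces["ILM"][b, ::2] / 2
        frac_close = (np.abs(zhat - ztrue) <= 2).mean()
        assert frac_close >= 0.9

    def test_recipe_mismatch_rejected(self, trained_stage1):
        model, stack, *_ = trained_stage1
        bad = cm.FeatureStack(stack.features, stack.z0, stack.z1, recipe_id="other")
        with pytest.raises(ValueError, match="recipe"):
            cm.predict_costs(model, bad)

    def test_model_round_trip(self, trained_stage1, tmp_path):
        model, stack, *_ = trained_stage1
        path = cm.save_model(model, tmp_path / "m.model")
        back = cm.load_model(path)
        assert back.classes == model.classes and back.mode == model.mode
        X = stack.matrix()[:1000]
        np.testing.assert_array_equal(back.forest.predict(X), model.forest.predict(X))
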