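"""Tests for the cohort generator: copula fidelity, phantom geometry,
signal model, determinism and rater perturbation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pt2nerve import (
    AcquisitionSpec,
    CovariateModel,
    CovariateSpec,
    GeometryConfig,
    GroupDistributions,
    LABEL_EPINEURIUM,
    LABEL_FASCICLE,
    NormalSpec,
    RunConfig,
    compute_pt2star,
    dice,
    icc_two_rater,
    roi_mean_pt2star,
    select_analysis_slices,
)
from pt2nerve.config import Marginal, default_covariate_model, default_group_distributions
from pt2nerve.morphometry import NerveLabelMap
from pt2nerve.simulate import (
    PackingError,
    SubjectTruth,
    build_label_map,
    build_phantom,
    draw_cohort_truth,
    draw_subject,
    generate_cohort,
    perturb_mask,
    render_echoes,
    spearman_to_latent,
)


def _single_cov_model(rho: float, kind: str = "lognormal") -> CovariateModel:
    marg = Marginal(kind, {"median": 8.0, "sigma": 0.6}) if kind == "lognormal" else Marginal(
        "normal", {"mean": 40.0, "sd": 5.0}
    )
    return CovariateModel(
        [CovariateSpec("probe", {"ATTRv": marg, "HC": marg}, {"ATTRv": rho, "HC": rho})]
    )


class TestDrawSubject:
    def test_degenerate_sd_returns_means_exactly(self):
        gd = GroupDistributions(
            fascicle_t2star=NormalSpec(14.74, 0.0),
            epineurium_t2star=NormalSpec(9.0, 0.0),
            csa_mm2=NormalSpec(37.89, 0.0),
            fascicular_fraction=NormalSpec(0.763, 0.0, ceil=0.95),
        )
        rng = np.random.default_rng(0)
        for _ in range(5):
            t = draw_subject("HC", {"HC": gd, "ATTRv": gd}, rng=rng)
            assert t.fascicle_t2star_ms == 14.74
            assert t.epineurium_t2star_ms == 9.0
            assert t.csa_mm2 == 37.89
            assert t.fascicular_fraction == 0.763

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="unknown group"):
            draw_subject("patients", default_group_distributions())

    def test_rank_correlation_bounds_enforced(self):
        with pytest.raises(ValueError, match="outside"):
            _single_cov_model(-1.2)
        with pytest.raises(ValueError):
            spearman_to_latent(1.5)

    def test_infeasible_truncation_rejected(self):
        with pytest.raises(ValueError, match="floor above mean"):
            NormalSpec(10.0, 1.0, floor=17.0)

    def test_copula_independence(self):
        model = _single_cov_model(0.0)
        rng = np.random.default_rng(11)
        gd = default_group_distributions()
        t2 = np.empty(2000)
        cov = np.empty(2000)
        for i in range(2000):
            t = draw_subject("ATTRv", gd, model, rng)
            t2[i], cov[i] = t.fascicle_t2star_ms, t.covariates["probe"]
        rho, _ = sps.spearmanr(t2, cov)
        assert abs(rho) < 0.05

    def test_copula_hits_published_tibial_cmap_target(self):
        """Default model: Spearman(fascicle pT2*, tibial CMAP) near the
        configured -0.715 at n=2000."""
        rng = np.random.default_rng(5)
        gd = default_group_distributions()
        model = default_covariate_model()
        t2 = np.empty(2000)
        cmap = np.empty(2000)
        for i in range(2000):
            t = draw_subject("ATTRv", gd, model, rng)
            t2[i], cmap[i] = t.fascicle_t2star_ms, t.covariates["cmap_tibial_mv"]
        rho, _ = sps.spearmanr(t2, cmap)
        assert rho == pytest.approx(-0.715, abs=0.05)

    @pytest.mark.parametrize("target", [-0.9, -0.5, 0.0, 0.5, 0.9])
    def test_copula_fidelity_sweep(self, target):
        """Continuous-marginal Spearman within +-0.03 of the target at
        n=5000."""
        model = _single_cov_model(target)
        rng = np.random.default_rng(17)
        gd = default_group_distributions()
        t2 = np.empty(5000)
        cov = np.empty(5000)
        for i in range(5000):
            t = draw_subject("ATTRv", gd, model, rng)
            t2[i], cov[i] = t.fascicle_t2star_ms, t.covariates["probe"]
        rho, _ = sps.spearmanr(t2, cov)
        assert rho == pytest.approx(target, abs=0.03)


class TestPhantom:
    def test_noiseless_two_echo_ratio(self, noiseless_subject):
        """At any fascicle voxel the noiseless iTE2/iTE1 ratio equals
        exp(-dTE / T2*), independent of amplitude."""
        truth, vol, mask = noiseless_subject
        fasc = mask.labels == LABEL_FASCICLE
        ratio = vol.echo2[fasc] / vol.echo1[fasc]
        expected = math.exp(-vol.delta_te_ms / truth.fascicle_t2star_ms)
        np.testing.assert_allclose(ratio, expected, rtol=1e-12)

    def test_fascicles_hyperintense_at_te1(self, noiseless_subject):
        truth, vol, mask = noiseless_subject
        f = vol.echo1[mask.labels == LABEL_FASCICLE].min()
        e = vol.echo1[mask.labels == LABEL_EPINEURIUM].max()
        assert f > e

    def test_rendered_geometry_matches_truth(self, noiseless_subject):
        truth, _, mask = noiseless_subject
        pix = mask.pixel_area_mm2
        for s in range(mask.nslices):
            nerve = np.isin(mask.labels[:, :, s], [LABEL_EPINEURIUM, LABEL_FASCICLE]).sum()
            fasc = (mask.labels[:, :, s] == LABEL_FASCICLE).sum()
            assert nerve * pix == pytest.approx(truth.csa_mm2, rel=0.05)
            assert fasc / nerve == pytest.approx(truth.fascicular_fraction, rel=0.05)

    def test_noiseless_end_to_end_identity(self):
        """Phantom -> pT2* map -> ROI mean reproduces the configured
        compartment decay times to <= 1e-9 relative error."""
        cfg = RunConfig(master_seed=1)
        cfg.geometry = GeometryConfig(shape=(64, 64, 4))
        cfg.acquisition = AcquisitionSpec(snr=math.inf)
        rng = np.random.default_rng(3)
        truth = draw_subject("ATTRv", cfg.groups, cfg.covariates, rng, subject_id="X")
        truth.fascicle_t2star_ms = 15.0
        vol, mask = build_phantom(truth, cfg.geometry, cfg.acquisition, rng=rng)
        pmap = compute_pt2star(vol)
        slices = select_analysis_slices(mask.nslices)
        fasc = roi_mean_pt2star(pmap, mask.labels, {LABEL_FASCICLE}, slices)
        epi = roi_mean_pt2star(pmap, mask.labels, {LABEL_EPINEURIUM}, slices)
        assert fasc.mean_ms == pytest.approx(15.0, rel=1e-9)
        assert epi.mean_ms == pytest.approx(truth.epineurium_t2star_ms, rel=1e-9)
        assert fasc.valid_fraction == 1.0

    def test_oversized_csa_rejected(self):
        t = SubjectTruth("X", "HC", 15.0, 9.0, csa_mm2=5000.0, fascicular_fraction=0.7)
        with pytest.raises(ValueError, match="does not fit"):
            build_label_map(t, GeometryConfig(), np.random.default_rng(0))

    def test_packing_failure_is_deterministic_error(self):
        t = SubjectTruth("X", "HC", 15.0, 9.0, csa_mm2=20.0, fascicular_fraction=0.7)
        with pytest.raises(PackingError):
            build_label_map(t, GeometryConfig(), np.random.default_rng(0), min_fascicles=500)

    def test_amplitude_scale_does_not_move_pt2star(self):
        """The two-echo ratio depends only on T2*, not amplitude."""
        from pt2nerve.config import CompartmentSpec

        cfg = GeometryConfig(shape=(48, 48, 3))
        acq = AcquisitionSpec(snr=math.inf)
        t = SubjectTruth("X", "HC", 13.0, 8.0, csa_mm2=30.0, fascicular_fraction=0.7)
        mask = build_label_map(t, cfg, np.random.default_rng(4))
        for scale in (1.0, 7.0):
            comps = {
                "fascicle": CompartmentSpec("fascicle", 18.0, 1.0 * scale),
                "epineurium": CompartmentSpec("epineurium", 9.0, 0.55 * scale),
                "muscle_background": CompartmentSpec("muscle_background", 25.0, 0.35 * scale),
            }
            vol = render_echoes(mask, t, acq, comps)
            pmap = compute_pt2star(vol)
            fasc = roi_mean_pt2star(pmap, mask.labels, {LABEL_FASCICLE}, (1,))
            assert fasc.mean_ms == pytest.approx(13.0, rel=1e-9)


class TestCohort:
    def test_truth_csv_deterministic(self, small_config, tmp_path):
        t1 = generate_cohort(small_config, tmp_path / "a", write_images=False)
        t2 = generate_cohort(small_config, tmp_path / "b", write_images=False)
        b1 = (tmp_path / "a" / "truth.csv").read_bytes()
        b2 = (tmp_path / "b" / "truth.csv").read_bytes()
        assert b1 == b2
        pd.testing.assert_frame_equal(t1, t2)

    def test_truth_matches_full_iteration(self, small_config):
        from pt2nerve.simulate import iter_cohort

        truth_only = draw_cohort_truth(small_config)
        truths = [t.as_row() for t, _, m in iter_cohort(small_config, with_images=False)]
        pd.testing.assert_frame_equal(truth_only, pd.DataFrame(truths, columns=truth_only.columns))

    def test_row_counts(self):
        cfg = RunConfig(master_seed=7, n_attrv=18, n_hc=21)
        table = draw_cohort_truth(cfg)
        assert len(table) == 39
        assert (table["group"] == "ATTRv").sum() == 18
        assert (table["group"] == "HC").sum() == 21

    def test_law_of_large_numbers_on_truth(self):
        """n=500 ATTRv: sample mean of true fascicle pT2* within
        2 sd / sqrt(500) of the configured mean (seed 7)."""
        cfg = RunConfig(master_seed=7, n_attrv=500, n_hc=1)
        table = draw_cohort_truth(cfg)
        attrv = table[table["group"] == "ATTRv"]["true_fascicle_t2star_ms"]
        spec = default_group_distributions()["ATTRv"].fascicle_t2star
        assert abs(attrv.mean() - spec.mean) <= 2 * spec.sd / math.sqrt(500)

    def test_label_maps_deterministic(self, small_config):
        from pt2nerve.simulate import iter_cohort

        m1 = [m.labels for _, _, m in iter_cohort(small_config, with_images=False)]
        m2 = [m.labels for _, _, m in iter_cohort(small_config, with_images=False)]
        for a, b in zip(m1, m2):
            np.testing.assert_array_equal(a, b)


@pytest.fixture(scope="module")
def disc_mask():
    x, y = np.meshgrid(np.arange(40), np.arange(40), indexing="ij")
    disc = ((x - 20) ** 2 + (y - 20) ** 2 <= 144).astype(np.int16) * LABEL_FASCICLE
    inner = (x - 20) ** 2 + (y - 20) ** 2 <= 36
    labels = disc.copy()
    labels[(disc > 0) & ~inner] = LABEL_EPINEURIUM
    return NerveLabelMap(labels=labels[:, :, None], voxel_mm=(0.6, 0.6, 5.0))


class TestPerturbMask:
    def test_rate_zero_is_identity(self, disc_mask):
        out = perturb_mask(disc_mask, 0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(out.labels, disc_mask.labels)
        assert dice(disc_mask, out, {LABEL_FASCICLE}) == 1.0
        # ICC of any derived measure across identical raters is 1
        vals = np.array([[1.0, 1.0], [2.0, 2.0], [3.5, 3.5]])
        assert icc_two_rater(vals).value == pytest.approx(1.0)

    def test_rate_perturbs_but_preserves_structure(self, disc_mask):
        out = perturb_mask(disc_mask, 0.2, np.random.default_rng(1))
        d = dice(disc_mask, out, {LABEL_FASCICLE})
        assert 0.0 < d < 1.0
        assert set(np.unique(out.labels)) <= {0, LABEL_EPINEURIUM, LABEL_FASCICLE}
        # only boundary voxels may change
        changed = out.labels != disc_mask.labels
        src = disc_mask.labels
        interior = np.ones_like(src, dtype=bool)
        for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
            interior &= np.roll(src, shift, axis=axis) == src
        assert not (changed & interior).any()

    def test_rate_bounds(self, disc_mask):
        with pytest.raises(ValueError):
            perturb_mask(disc_mask, 0.6, np.random.default_rng(0))
        with pytest.raises(ValueError):
            perturb_mask(disc_mask, -0.1, np.random.default_rng(0))
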