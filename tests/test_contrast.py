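"""GLM t-maps, smoothness estimation and cluster-level correction."""

import numpy as np
import pytest
from scipy import ndimage

from imgx.contrast import (estimate_smoothness, grf_cluster_correct,
                           overlap_maps, permutation_cluster_correct,
                           resel_counts, voxelwise_glm_t)
from imgx.synthetic import FWHM_TO_SIGMA, CohortSpec, EffectCluster, make_cohort
from imgx.types import VolumetricMap

EYE = np.diag([1.5, 1.5, 1.5, 1.0])


def _const_vols(values):
    """One 2x2x2 constant volume per subject value."""
    return [VolumetricMap(np.full((2, 2, 2), v), EYE,
                          np.ones((2, 2, 2), bool)) for v in values]


def test_two_sample_t_closed_form():
    """{1,2,3} vs {4,5,6}: pooled-variance t = -3.674, df = 4."""
    res = voxelwise_glm_t(_const_vols([1, 2, 3]), _const_vols([4, 5, 6]))
    assert res.df == 4
    np.testing.assert_allclose(res.t_map.values, -3.0 / np.sqrt(2.0 / 3.0),
                               rtol=1e-10)


def test_identical_groups_give_zero_t():
    vols = _const_vols([1.0, 2.0, 1.5, 0.5])
    res = voxelwise_glm_t(vols, vols)
    np.testing.assert_allclose(res.t_map.values, 0.0, atol=1e-10)


def test_gender_covariate_df():
    """n = 83 + 83 with intercept + group + gender: df = 163."""
    rng = np.random.default_rng(0)
    mk = lambda: [VolumetricMap(rng.standard_normal((3, 3, 3)), EYE,
                                np.ones((3, 3, 3), bool)) for _ in range(83)]
    cov = rng.integers(0, 2, 166).astype(float)[:, None]
    res = voxelwise_glm_t(mk(), mk(), cov)
    assert res.df == 163


def test_label_swap_negates_t_and_shift_invariance():
    rng = np.random.default_rng(1)
    a = [VolumetricMap(rng.standard_normal((4, 4, 4)), EYE,
                       np.ones((4, 4, 4), bool)) for _ in range(6)]
    b = [VolumetricMap(rng.standard_normal((4, 4, 4)), EYE,
                       np.ones((4, 4, 4), bool)) for _ in range(6)]
    full = np.ones((4, 4, 4), bool)
    t_ab = voxelwise_glm_t(a, b, mask=full).t_map.values
    t_ba = voxelwise_glm_t(b, a, mask=full).t_map.values
    np.testing.assert_allclose(t_ab, -t_ba, atol=1e-10)
    shift = lambda vols: [VolumetricMap(v.values + 7.5, EYE, v.mask)
                          for v in vols]
    t_shift = voxelwise_glm_t(shift(a), shift(b), mask=full).t_map.values
    np.testing.assert_allclose(t_ab, t_shift, atol=1e-8)


def test_rank_deficient_design_rejected():
    a = _const_vols([1, 2, 3])
    b = _const_vols([4, 5, 6])
    cov = np.r_[np.ones(3), np.zeros(3)][:, None]   # duplicates the group column
    with pytest.raises(ValueError, match="rank-deficient"):
        voxelwise_glm_t(a, b, cov)


def test_mismatched_grids_rejected():
    a = _const_vols([1, 2, 3])
    bad = VolumetricMap(np.zeros((3, 3, 3)), EYE)
    with pytest.raises(ValueError, match="share grid"):
        voxelwise_glm_t(a, [bad, bad, bad])


# ---------------------------------------------------------------------------
# smoothness
# ---------------------------------------------------------------------------

def _smooth_residuals(rng, n, shape, fwhm_mm, voxel=1.5):
    sigma = fwhm_mm * FWHM_TO_SIGMA / voxel
    out = np.empty((n, *shape))
    for i in range(n):
        out[i] = ndimage.gaussian_filter(rng.standard_normal(shape),
                                         sigma, mode="wrap")
    return out


def test_smoothness_recovers_applied_fwhm():
    rng = np.random.default_rng(2)
    shape = (32, 32, 32)
    mask = np.ones(shape, bool)
    vs = np.array([1.5, 1.5, 1.5])
    res = _smooth_residuals(rng, 20, shape, 8.0)
    est = estimate_smoothness(res, mask, vs)
    assert np.all(np.abs(est - 8.0) < 0.15 * 8.0)


def test_smoothness_monotone_in_applied_smoothing():
    rng = np.random.default_rng(3)
    shape = (32, 32, 32)
    mask = np.ones(shape, bool)
    vs = np.array([1.5, 1.5, 1.5])
    ests = []
    for fwhm in (0.0, 4.0, 8.0):
        res = (_smooth_residuals(rng, 12, shape, fwhm) if fwhm
               else rng.standard_normal((12, *shape)))
        ests.append(estimate_smoothness(res, mask, vs).mean())
    assert ests[0] < ests[1] < ests[2]


def test_smoothness_rejects_flat_or_single_residual():
    mask = np.ones((4, 4, 4), bool)
    vs = np.ones(3)
    with pytest.raises(ValueError, match=">= 2"):
        estimate_smoothness(np.zeros((1, 4, 4, 4)), mask, vs)
    with pytest.raises(ValueError, match="flat"):
        estimate_smoothness(np.zeros((3, 4, 4, 4)), mask, vs)


def test_resel_counts_full_box():
    """For a full box the top resel count is (cubes) / prod(FWHM)."""
    mask = np.ones((5, 6, 7), bool)
    r = resel_counts(mask, np.array([2.0, 2.0, 2.0]))
    assert r[3] == pytest.approx(4 * 5 * 6 / 8.0)
    assert r[0] == 1.0   # Euler characteristic of a solid box


# ---------------------------------------------------------------------------
# cluster correction
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def null_contrast():
    spec = CohortSpec(grid_shape=(32, 32, 32), n_per_group=12,
                      groups=("A", "B"), seed=21)
    cohort = make_cohort(spec)
    return voxelwise_glm_t(cohort.maps("A"), cohort.maps("B"))


def test_subthreshold_map_gives_empty_masks(null_contrast):
    res = null_contrast
    flat = VolumetricMap(np.clip(res.t_map.values, -1, 1), res.t_map.affine,
                         res.t_map.mask)
    out = grf_cluster_correct(
        type(res)(name=res.name, t_map=flat, df=res.df,
                  n_subjects=res.n_subjects, residuals=res.residuals))
    assert not out.mask_neg.any() and not out.mask_pos.any()


def test_cluster_p_nesting(planted_cohort):
    cohort = planted_cohort
    res = voxelwise_glm_t(cohort.maps("AD"), cohort.maps("NC"))
    strict = grf_cluster_correct(res, cluster_p=0.01)
    res2 = voxelwise_glm_t(cohort.maps("AD"), cohort.maps("NC"))
    loose = grf_cluster_correct(res2, cluster_p=0.20)
    assert (strict.mask_neg <= loose.mask_neg).all()
    assert strict.cluster_table["retained"].sum() \
        <= loose.cluster_table["retained"].sum()


def test_planted_cluster_survives_correction(planted_cohort):
    cohort = planted_cohort
    res = voxelwise_glm_t(cohort.maps("AD"), cohort.maps("NC"))
    out = grf_cluster_correct(res)
    assert out.mask_neg[10, 16, 16]
    retained = out.cluster_table.query("retained and sign == 'neg'")
    assert len(retained) >= 1
    assert retained["cluster_p"].min() < 0.05


def test_fwhm_clamped_with_warning(null_contrast):
    with pytest.warns(UserWarning, match="clamping"):
        out = grf_cluster_correct(null_contrast, fwhm_mm=0.5)
    np.testing.assert_allclose(out.fwhm_mm, 1.5)


def test_permutation_alternative_finds_planted_cluster():
    spec = CohortSpec(grid_shape=(24, 24, 24), n_per_group=15,
                      groups=("NC", "AD"),
                      effect_clusters=[EffectCluster((8, 12, 12), 6.0,
                                                     {"AD": -2.0})], seed=13)
    cohort = make_cohort(spec)
    res = permutation_cluster_correct(cohort.maps("AD"), cohort.maps("NC"),
                                      n_perm=60, seed=1)
    assert res.mask_neg[8, 12, 12]


# ---------------------------------------------------------------------------
# overlap
# ---------------------------------------------------------------------------

def test_overlap_idempotent_and_empty():
    m = np.zeros((3, 3, 3), bool)
    m[1, 1, 1] = True
    np.testing.assert_array_equal(overlap_maps([m, m, m]), m)
    assert not overlap_maps([m, np.zeros_like(m)]).any()
    with pytest.raises(ValueError, match="share grid"):
        overlap_maps([m, np.zeros((2, 2, 2), bool)])


def test_overlap_contains_planted_cluster(recovery_run):
    masks = [r.mask_neg for r in recovery_run["contrasts"].values()]
    ov = overlap_maps(masks)
    center = recovery_run["cohort_spec"].effect_clusters[0].center_vox
    assert ov[center]
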