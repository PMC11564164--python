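"""Expression-reduction steps: probe filters, hemisphere rule, SRS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from imgx.expression import (DonorExpressionSet, build_expression_matrix,
                             filter_left_hemisphere,
                             filter_probes_by_background,
                             intersect_risk_genes, normalize_expression,
                             robust_sigmoid, scaled_robust_sigmoid,
                             select_probes_by_rnaseq)


# ---------------------------------------------------------------------------
# background filter
# ---------------------------------------------------------------------------

def _pa(rows):
    return pd.DataFrame(rows, index=[f"p{i}" for i in range(len(rows))])


@pytest.mark.parametrize("present,expected", [
    ([1, 1, 1, 0, 0], True),    # 3/5 >= 0.5 -> retained
    ([1, 1, 0, 0, 0], False),   # 2/5 < 0.5 -> removed
    ([1, 1, 1, 1, 1], True),    # present everywhere
])
def test_background_filter_fraction_rule(present, expected):
    kept = filter_probes_by_background(_pa([present]))
    assert ("p0" in kept) == expected


def test_background_filter_exact_half_and_everywhere():
    pa = _pa([[1, 1, 1, 0, 0],    # 3/5 retained
              [1, 1, 0, 0, 0],    # 2/5 removed
              [1, 1, 1, 1, 1]])   # everywhere
    kept = filter_probes_by_background(pa)
    assert list(kept) == ["p0", "p2"]
    assert "p2" in filter_probes_by_background(pa, min_fraction=1.0)
    with pytest.raises(ValueError, match="empty"):
        filter_probes_by_background(pa.iloc[:0, :0])
    with pytest.raises(ValueError, match="binary"):
        filter_probes_by_background(_pa([[0.5, 1, 1]]))


def test_background_filter_pools_across_donors():
    a = _pa([[1, 1]])
    b = _pa([[0, 0, 0]])
    assert len(filter_probes_by_background([a, b])) == 0   # 2/5 pooled
    assert len(filter_probes_by_background([a, _pa([[1, 0, 0]])])) == 1


# ---------------------------------------------------------------------------
# RNA-seq probe selection
# ---------------------------------------------------------------------------

def test_rnaseq_selection_picks_best_correlated_probe():
    rng = np.random.default_rng(0)
    ref = rng.standard_normal(30)
    wells = np.arange(30)
    expr = pd.DataFrame(
        [ref + 0.2 * rng.standard_normal(30),      # r ~ 0.9
         rng.standard_normal(30),                  # r ~ 0
         ref + 0.1 * rng.standard_normal(30)],     # single-probe gene
        index=[101, 102, 201], columns=wells)
    probes = pd.DataFrame({"gene_symbol": ["GA", "GA", "GB"]},
                          index=pd.Index([101, 102, 201], name="probe_id"))
    rnaseq = pd.DataFrame([ref, ref], index=["GA", "GB"], columns=wells)
    chosen = select_probes_by_rnaseq(expr, probes, rnaseq)
    assert chosen["GA"] == 101
    assert chosen["GB"] == 201


def test_rnaseq_selection_drops_uncovered_genes():
    wells = np.arange(10)
    expr = pd.DataFrame(np.random.default_rng(1).standard_normal((2, 10)),
                        index=[1, 2], columns=wells)
    probes = pd.DataFrame({"gene_symbol": ["GA", "GB"]},
                          index=pd.Index([1, 2], name="probe_id"))
    rnaseq = pd.DataFrame([expr.loc[1]], index=["GA"], columns=wells)
    chosen = select_probes_by_rnaseq(expr, probes, rnaseq)
    assert list(chosen.index) == ["GA"]


def test_high_fidelity_probe_selected_for_planted_genes(small_expression):
    """The generator's probe 0 (high fidelity) wins for >= 95% of genes."""
    synth = small_expression["synth"]
    pooled = pd.concat([d.expression for d in synth.donors], axis=1)
    probes = synth.donors[0].probes
    chosen = select_probes_by_rnaseq(pooled, probes, synth.rnaseq)
    first_probe = {g: grp.index.min()
                   for g, grp in probes.groupby("gene_symbol")}
    hit = np.mean([chosen[g] == first_probe[g] for g in chosen.index])
    assert hit >= 0.95


# ---------------------------------------------------------------------------
# hemisphere filter
# ---------------------------------------------------------------------------

def test_left_hemisphere_rule_signs_and_midline():
    samples = pd.DataFrame({"mni_x": [-30.0, 30.0, 0.0, -0.01]},
                           index=[1, 2, 3, 4])
    kept = filter_left_hemisphere(samples)
    assert list(kept) == [1, 4]


def test_left_hemisphere_missing_coordinate_warns():
    samples = pd.DataFrame({"mni_x": [-5.0, np.nan]}, index=[1, 2])
    with pytest.warns(UserWarning, match="missing mni_x"):
        kept = filter_left_hemisphere(samples)
    assert list(kept) == [1]


def test_left_filter_keeps_about_half_of_generated_samples(small_expression):
    synth = small_expression["synth"]
    kept = filter_left_hemisphere(synth.samples)
    frac = len(kept) / len(synth.samples)
    assert 0.45 < frac < 0.55


# ---------------------------------------------------------------------------
# SRS normalization
# ---------------------------------------------------------------------------

def test_robust_sigmoid_maps_median_to_half():
    x = np.array([3.0, 1.0, 10.0, 2.0, 7.0])
    s = robust_sigmoid(x)
    assert s[np.argsort(x)[2]] == pytest.approx(0.5)


@given(st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=40))
def test_srs_unit_interval_and_rank_preserving(values):
    x = np.asarray(values)
    s = scaled_robust_sigmoid(x)
    assert np.all((s >= 0) & (s <= 1))
    # monotone transform: order preserved (ties allowed only where the
    # sigmoid saturates in float precision)
    order = np.argsort(x, kind="stable")
    assert np.all(np.diff(s[order]) >= 0)


def test_srs_preserves_ranks_on_typical_intensities():
    rng = np.random.default_rng(11)
    x = rng.normal(7.5, 1.5, size=200)     # log2-intensity scale
    s = scaled_robust_sigmoid(x)
    np.testing.assert_array_equal(stats.rankdata(s), stats.rankdata(x))


def test_srs_affine_invariance_across_donors():
    """Two donors identical up to location/scale normalize identically."""
    rng = np.random.default_rng(2)
    base = pd.DataFrame(rng.standard_normal((25, 4)),
                        index=np.arange(25), columns=list("ABCD"))
    shifted = 3.0 + 1.7 * base
    shifted.index = np.arange(100, 125)
    out = normalize_expression({"d1": base, "d2": shifted})
    np.testing.assert_allclose(out.values.loc[base.index].to_numpy(),
                               out.values.loc[shifted.index].to_numpy(),
                               atol=1e-12)


def test_srs_idempotent_at_rank_level():
    rng = np.random.default_rng(3)
    x = rng.standard_normal(50)
    once = scaled_robust_sigmoid(x)
    twice = scaled_robust_sigmoid(once)
    np.testing.assert_array_equal(stats.rankdata(once), stats.rankdata(twice))


def test_srs_zero_iqr_fallback():
    x = np.array([1.0] * 10 + [2.0, 3.0])   # IQR = 0, not constant
    s = scaled_robust_sigmoid(x)
    assert np.all((s >= 0) & (s <= 1))
    assert s[-1] > s[-2] > s[0]
    assert np.all(scaled_robust_sigmoid(np.ones(5)) == 0.5)


def test_normalization_is_order_stable():
    """Permuting input sample rows permutes output rows identically."""
    rng = np.random.default_rng(4)
    mat = pd.DataFrame(rng.standard_normal((20, 3)),
                       index=np.arange(20), columns=list("XYZ"))
    perm = rng.permutation(20)
    out1 = normalize_expression({"d": mat}).values
    out2 = normalize_expression({"d": mat.iloc[perm]}).values
    pd.testing.assert_frame_equal(out1.loc[out2.index], out2)


# ---------------------------------------------------------------------------
# risk-gene intersection
# ---------------------------------------------------------------------------

def test_risk_intersection_counts_and_order():
    risk = [f"R{i}" for i in range(52)]
    background = [f"R{i}" for i in range(41)] + ["OTHER1", "OTHER2"]
    out = intersect_risk_genes(risk, background)
    assert len(out) == 41
    assert out == risk[:41]


def test_risk_intersection_identity_case_and_whitespace():
    assert intersect_risk_genes([" apoe ", "CD33"],
                                ["APOE", "CD33", "X"]) == ["APOE", "CD33"]


def test_risk_intersection_disjoint_errors():
    with pytest.raises(ValueError, match="disjoint"):
        intersect_risk_genes(["A"], ["B"])


# ---------------------------------------------------------------------------
# end-to-end reduction invariants
# ---------------------------------------------------------------------------

def test_built_matrix_respects_invariants(small_expression):
    mat = small_expression["matrix"]
    v = mat.values.to_numpy()
    assert v.min() >= 0 and v.max() <= 1
    assert not np.isnan(v).any()
    assert (mat.samples["mni_x"] < 0).all()
    assert mat.values.columns.is_unique


def test_donor_set_shape_validation():
    expr = pd.DataFrame(np.ones((2, 3)), index=[1, 2], columns=[10, 11, 12])
    pa = pd.DataFrame(np.ones((2, 2)), index=[1, 2], columns=[10, 11])
    probes = pd.DataFrame({"gene_symbol": ["A", "B"]},
                          index=pd.Index([1, 2], name="probe_id"))
    ann = pd.DataFrame({"mni_x": [-1, -2, -3]},
                       index=pd.Index([10, 11, 12], name="well_id"))
    with pytest.raises(ValueError, match="share shape"):
        DonorExpressionSet("d", probes, expr, pa, ann)


def test_donor_roundtrip_through_files(tmp_path, small_expression):
    donor = small_expression["synth"].donors[0]
    donor.write(tmp_path / "donor_D01")
    back = DonorExpressionSet.read(tmp_path / "donor_D01")
    np.testing.assert_allclose(back.expression.to_numpy(),
                               donor.expression.to_numpy(), rtol=1e-12)
    assert list(back.samples.index) == list(donor.samples.index)
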