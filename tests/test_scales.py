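"""Scale triples for the six parameterizations and their orthogonality
structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grmforge import (
    GenotypeFrequencies,
    GenotypeMatrix,
    MarkerScales,
    build_scale_matrices,
    compute_frequencies,
    compute_scales,
    gspa_scales,
    gspd_scales,
    gspn_scales,
    hw_scales,
    marker_angle,
    nohw_scales,
    noia_scales,
    verify_orthogonality,
)
from grmforge.genotypes import MISSING

from conftest import freqs, panel_from_counts, random_simplex

simplex_triples = st.tuples(
    st.floats(0.01, 0.97), st.floats(0.01, 0.97), st.floats(0.01, 0.97)
).map(lambda t: tuple(x / sum(t) for x in t))


# ----------------------------------------------------------- exact triples


@pytest.mark.parametrize(
    "p, additive, dominance, sc_a, sc_d",
    [
        (0.5, (1, 0, -1), (-0.5, 0.5, -0.5), 0.5, 0.25),
        (0.25, (1.5, 0.5, -0.5), (-0.375, 0.625, -0.375), 0.375, 0.234375),
    ],
)
def test_hw_triples(p, additive, dominance, sc_a, sc_d):
    f = GenotypeFrequencies.from_proportions([p * p], [2 * p * (1 - p)], [(1 - p) ** 2])
    s = hw_scales(f)
    np.testing.assert_allclose(s.additive[0], additive, atol=1e-12)
    np.testing.assert_allclose(s.dominance[0], dominance, atol=1e-12)
    assert s.sc_a_contrib[0] == pytest.approx(sc_a)
    assert s.sc_d_contrib[0] == pytest.approx(sc_d)


def test_hw_fixed_allele_is_degenerate():
    f = freqs(1.0, 0.0, 0.0)  # p = 1
    s = hw_scales(f)
    assert not s.additive_ok[0] and not s.dominance_ok[0]
    # the raw formula gives additive (0, -1, -2) before masking
    p = f.p[0]
    np.testing.assert_allclose([2 - 2 * p, 1 - 2 * p, -2 * p], [0, -1, -2])


@pytest.mark.parametrize(
    "triple, additive, sc_a",
    [
        ((0.25, 0.5, 0.25), (1, 0, -1), 0.5),  # reduces to HW at p = 0.5
        ((0.5, 0.3, 0.2), (0.7, -0.3, -1.3), 0.61),
    ],
)
def test_nohw_additive(triple, additive, sc_a):
    s = nohw_scales(freqs(*triple))
    np.testing.assert_allclose(s.additive[0], additive, atol=1e-12)
    assert s.sc_a_contrib[0] == pytest.approx(sc_a, abs=1e-12)


def test_nohw_all_heterozygous_dominance():
    s = nohw_scales(freqs(0.0, 1.0, 0.0))
    np.testing.assert_allclose(s.dominance[0], [-1, 0, -1])
    assert s.sc_d_contrib[0] == 0.0
    assert not s.dominance_ok[0]


def test_noia_dominance_values():
    s = noia_scales(freqs(0.25, 0.5, 0.25))
    np.testing.assert_allclose(s.dominance[0], (-0.5, 0.5, -0.5), atol=1e-12)
    s = noia_scales(freqs(0.5, 0.3, 0.2))
    assert s.dominance[0, 0] == pytest.approx(-(2 * 0.3 * 0.2) / 0.61, abs=1e-6)


@pytest.mark.parametrize(
    "triple, additive, sc_a",
    [
        ((0.5, 0.3, 0.2), (2 * 0.2 / 0.7, 0.0, -2 * 0.5 / 0.7), 4 * 0.5 * 0.2 / 0.7),
        ((0.25, 0.5, 0.25), (1, 0, -1), 0.5),
    ],
)
def test_gspd_additive(triple, additive, sc_a):
    s = gspd_scales(freqs(*triple))
    np.testing.assert_allclose(s.additive[0], additive, atol=1e-12)
    assert s.sc_a_contrib[0] == pytest.approx(sc_a, abs=1e-12)
    assert s.additive[0, 1] == 0.0  # heterozygote additive scale exactly 0


def test_gspd_all_heterozygous_has_no_additive_scale():
    s = gspd_scales(freqs(0.0, 1.0, 0.0))
    assert not s.additive_ok[0]
    np.testing.assert_array_equal(s.additive[0], 0.0)


def test_gspa_projection_vanishes_at_equal_homozygotes():
    s = gspa_scales(freqs(0.4, 0.2, 0.4))
    np.testing.assert_allclose(s.dominance[0], (-0.2, 0.8, -0.2), atol=1e-12)


def test_gspn_normalization():
    f = freqs(0.5, 0.3, 0.2)
    n = 100
    s = gspn_scales(f, n)
    base = gspa_scales(f)
    norm_a = np.sqrt(n * 0.61)
    assert norm_a == pytest.approx(7.8102, abs=1e-4)
    np.testing.assert_allclose(s.additive[0], base.additive[0] / norm_a, atol=1e-12)
    # unit length: n * sum_g p_g u_g^2 = 1
    w = np.array([0.5, 0.3, 0.2])
    assert n * (w * s.additive[0] ** 2).sum() == pytest.approx(1.0, abs=1e-10)
    assert n * (w * s.dominance[0] ** 2).sum() == pytest.approx(1.0, abs=1e-10)


# ------------------------------------------------- cross-method identities


@given(simplex_triples)
@settings(max_examples=300, deadline=None)
def test_orthogonality_conditions_per_method(triple):
    """Centering residuals vanish for every non-HW method, and the
    frequency-weighted additive-dominance inner product vanishes for the
    orthogonalized ones."""
    f = freqs(*triple)
    for method in ("nohw", "noia", "gspa", "gspd", "gspn"):
        s = compute_scales(f, method, n=100)
        r = verify_orthogonality(s, f)
        assert abs(r["additive_residual"][0]) < 1e-10
        assert abs(r["dominance_residual"][0]) < 1e-10
        if method != "nohw":
            assert abs(r["cross_residual"][0]) < 1e-10


@given(simplex_triples)
@settings(max_examples=300, deadline=None)
def test_gspa_dominance_equals_noia(triple):
    f = freqs(*triple)
    np.testing.assert_allclose(
        gspa_scales(f).dominance, noia_scales(f).dominance, atol=1e-10
    )
    np.testing.assert_allclose(
        gspa_scales(f).additive, nohw_scales(f).additive, atol=1e-12
    )


@given(simplex_triples)
@settings(max_examples=200, deadline=None)
def test_additive_allele_substitution_structure(triple):
    """Consecutive genotype differences equal 1 for the centered additive
    scales (one allele substitution apart)."""
    f = freqs(*triple)
    for fn in (nohw_scales, noia_scales, gspa_scales):
        u = fn(f).additive[0]
        assert u[0] - u[1] == pytest.approx(1.0, abs=1e-12)
        assert u[1] - u[2] == pytest.approx(1.0, abs=1e-12)


@given(st.floats(0.05, 0.95))
@settings(max_examples=100, deadline=None)
def test_hwe_limit_reductions(p):
    """At (p^2, 2pq, q^2) the frequency-centered dominance triple equals the
    classical genotypic coding (-2pq, 1-2pq, -2pq) with SC contribution
    2pq(1-2pq), while the orthogonalized (NOIA) dominance triple reduces to
    the statistical dominance coding (-2q^2, 2pq, -2p^2)."""
    q = 1 - p
    f = GenotypeFrequencies.from_proportions([p * p], [2 * p * q], [q * q])
    s_nohw, s_hw = nohw_scales(f), hw_scales(f)
    np.testing.assert_allclose(s_nohw.dominance, s_hw.dominance, atol=1e-9)
    assert s_nohw.sc_d_contrib[0] == pytest.approx(
        2 * p * q * (1 - 2 * p * q), abs=1e-9
    )
    np.testing.assert_allclose(
        noia_scales(f).dominance[0],
        [-2 * q * q, 2 * p * q, -2 * p * p],
        atol=1e-9,
    )


def test_nohw_cross_residual_matches_inner_product_expectation():
    f = freqs(0.5, 0.3, 0.2)
    r = verify_orthogonality(nohw_scales(f), f)
    assert r["cross_residual"][0] == pytest.approx(-0.3 * (0.5 - 0.2), abs=1e-12)
    assert r["cross_residual"][0] == pytest.approx(-0.09)
    assert not r["orthogonal"]


def test_gspa_sc_d_equals_weighted_squared_tau(f1_frequencies):
    s = gspa_scales(f1_frequencies)
    f = f1_frequencies
    w = np.column_stack([f.p_AA, f.p_Aa, f.p_aa])
    realized = (w * s.dominance**2).sum(axis=1)
    np.testing.assert_allclose(realized[s.dominance_ok], s.sc_d_contrib[s.dominance_ok], atol=1e-10)


# ------------------------------------------------------------ scale matrices


def test_build_scale_matrices_two_individuals_nohw():
    g = GenotypeMatrix(["A", "B"], ["m1"], np.array([[2], [0]]))
    sm = build_scale_matrices(g, "nohw")
    np.testing.assert_allclose(sm.Ha[:, 0], [1.0, -1.0])
    assert sm.SC_a == pytest.approx(1.0)


def test_columns_sum_to_zero_on_complete_data(f1_panel):
    for method in ("nohw", "noia", "gspa", "gspd", "gspn"):
        sm = build_scale_matrices(f1_panel, method)
        np.testing.assert_allclose(sm.Ha.sum(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(sm.Hd.sum(axis=0), 0.0, atol=1e-9)


def test_hw_dominance_column_mean_is_het_minus_2pq():
    g = panel_from_counts(0, 4, 0)  # all heterozygous, pAa = 1, p = 0.5
    sm = build_scale_matrices(g, "hw")
    assert sm.Hd[:, 0].mean() == pytest.approx(1.0 - 2 * 0.5 * 0.5)  # = 0.5


def test_missing_genotypes_become_zero_and_columns_stay_centered():
    codes = np.array([[2], [1], [0], [MISSING]])
    g = GenotypeMatrix(list("ABCD"), ["m1"], codes)
    sm = build_scale_matrices(g, "nohw")
    assert sm.Ha[3, 0] == 0.0 and sm.Hd[3, 0] == 0.0
    assert sm.Ha[:, 0].sum() == pytest.approx(0.0, abs=1e-12)


def test_all_markers_degenerate_is_an_error():
    g = GenotypeMatrix(["A", "B"], ["m1"], np.array([[2], [2]]))
    with pytest.raises(ValueError, match="degenerate"):
        build_scale_matrices(g, "noia")


def test_gspn_markers_contribute_equally_to_trace(f1_panel):
    sm = build_scale_matrices(f1_panel, "gspn")
    per_marker = (sm.Ha**2).sum(axis=0)
    keep = sm.scale_set.additive_ok
    np.testing.assert_allclose(per_marker[keep], 1.0, atol=1e-10)
    assert sm.denominator_mode == "realized_trace"


# ------------------------------------------------------------------ angles


def test_angle_example():
    rep = marker_angle(freqs(0.5, 0.3, 0.2), 100)
    assert rep.cos_theta[0] == pytest.approx(-0.09 / np.sqrt(0.61 * 0.21), abs=1e-6)
    expected = np.degrees(np.arccos(-0.09 / np.sqrt(0.61 * 0.21)))
    assert expected == pytest.approx(104.564, abs=1e-3)
    assert rep.theta_degrees[0] == pytest.approx(expected, abs=1e-9)


def test_angle_numeric_oracle():
    """The closed-form angle matches the angle between explicitly
    constructed 100-individual scale vectors."""
    n_AA, n_Aa, n_aa = 50, 30, 20
    g = panel_from_counts(n_AA, n_Aa, n_aa)
    f = compute_frequencies(g)
    sm = build_scale_matrices(
        GenotypeMatrix(
            [f"i{k}" for k in range(100)],
            ["m1"],
            np.array([[2]] * n_AA + [[1]] * n_Aa + [[0]] * n_aa),
        ),
        "nohw",
    )
    u, v = sm.Ha[:, 0], sm.Hd[:, 0]
    cos = (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
    rep = marker_angle(f, 100)
    assert rep.cos_theta[0] == pytest.approx(cos, abs=1e-12)
    assert rep.inner_product[0] == pytest.approx(u @ v, abs=1e-9)


def test_angle_is_independent_of_n():
    f = freqs(0.5, 0.3, 0.2)
    assert marker_angle(f, 10).theta_degrees[0] == pytest.approx(
        marker_angle(f, 10_000).theta_degrees[0], abs=1e-12
    )


def test_angle_ninety_iff_equal_homozygotes():
    grid = np.linspace(0.05, 0.9, 12)
    rng = np.random.default_rng(3)
    for _ in range(200):
        t = random_simplex(rng, 1)[0]
        theta = marker_angle(freqs(*t), 50).theta_degrees[0]
        if abs(t[0] - t[2]) < 1e-12:
            assert theta == pytest.approx(90.0, abs=1e-9)
        else:
            assert abs(theta - 90.0) > 1e-9
    for h in grid:  # equal homozygotes along a grid
        t = ((1 - h) / 2, h, (1 - h) / 2)
        assert marker_angle(freqs(*t), 50).theta_degrees[0] == pytest.approx(90.0)


# ------------------------------------------------------------- estimator API


def test_marker_scales_transformer_roundtrip(f1_panel):
    est = MarkerScales(method="noia", component="dominance")
    H = est.fit_transform(f1_panel.codes)
    sm = build_scale_matrices(f1_panel, "noia")
    np.testing.assert_allclose(H, sm.Hd)
    # transform of new individuals reuses the fitted frequencies
    H2 = est.transform(f1_panel.codes[:5])
    np.testing.assert_allclose(H2, sm.Hd[:5])
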