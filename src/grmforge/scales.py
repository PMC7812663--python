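"""Per-marker additive and dominance scales for six parameterizations.

A "scale" assigns one coefficient to each of the three genotypes AA, Aa, aa
of a marker, chosen so the marker's column in the centered incidence matrix
has zero mean (like a contrast). Six constructions are provided:

``hw``
    VanRaden additive centering (2-2p, 1-2p, -2p) and the Su/Vitezica
    dominance centering (-2pq, 1-2pq, -2pq); both assume Hardy-Weinberg
    genotype frequencies and fail to center otherwise.
``nohw``
    Centering by the observed genotype frequencies: additive
    (1-D, -D, -1-D) with D = pAA - paa, dominance (-pAa, 1-pAa, -pAa).
    Centered under any frequencies but additive/dominance scales may be
    correlated.
``noia``
    The natural-and-orthogonal-interactions scales: additive as ``nohw``,
    dominance rescaled so the frequency-weighted additive x dominance inner
    product is zero. Relationship matrices are scaled by the realized trace.
``gspa`` / ``gspd``
    Gram-Schmidt orthogonalization keeping the additive (``gspa``) or the
    dominance (``gspd``) vector fixed and projecting the common component out
    of the other. ``gspa`` reproduces the NOIA scales algebraically but uses
    the expected (frequency-based) trace for scaling.
``gspn``
    The ``gspa`` basis normalized to unit vector length per marker, so every
    marker contributes equally to the relationship matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .genotypes import MISSING, GenotypeFrequencies, GenotypeMatrix, compute_frequencies

DEGENERACY_TOL = 1e-12

METHODS = ("hw", "nohw", "noia", "gspa", "gspd", "gspn")

#: scaling-denominator convention per method: sum of expected per-marker
#: variance contributions, or the realized trace tr(HH')/n
DENOMINATOR_MODE = {
    "hw": "expected_sum",
    "nohw": "expected_sum",
    "noia": "realized_trace",
    "gspa": "expected_sum",
    "gspd": "expected_sum",
    "gspn": "realized_trace",
}

_ALIASES = {
    "hw": "hw",
    "no-hw": "nohw",
    "nohw": "nohw",
    "noia": "noia",
    "gsp-a": "gspa",
    "gspa": "gspa",
    "gsp-d": "gspd",
    "gspd": "gspd",
    "gsp-n": "gspn",
    "gspn": "gspn",
}

__all__ = [
    "METHODS",
    "DENOMINATOR_MODE",
    "MarkerScaleSet",
    "ScaleMatrices",
    "OrthogonalityReport",
    "MarkerScales",
    "normalize_method",
    "hw_scales",
    "nohw_scales",
    "noia_scales",
    "gspa_scales",
    "gspd_scales",
    "gspn_scales",
    "compute_scales",
    "build_scale_matrices",
    "marker_angle",
    "verify_orthogonality",
]


def normalize_method(method: str) -> str:
    key = str(method).strip().lower().replace("_", "-")
    key = _ALIASES.get(key, _ALIASES.get(key.replace("-", "")))
    if key is None:
        raise ValueError(f"unknown method {method!r}; valid: {', '.join(METHODS)}")
    return key


@dataclass
class MarkerScaleSet:
    """Additive/dominance genotype triples and scaling contributions.

    ``additive`` and ``dominance`` are (m, 3) arrays with columns ordered
    (AA, Aa, aa). ``sc_a_contrib``/``sc_d_contrib`` are each marker's
    expected contribution to the scaling denominator. Markers whose
    method-specific variance weight falls below a degeneracy tolerance are
    masked out (``additive_ok``/``dominance_ok``) with zeroed rows.
    """

    method: str
    additive: np.ndarray
    dominance: np.ndarray
    sc_a_contrib: np.ndarray
    sc_d_contrib: np.ndarray
    additive_ok: np.ndarray
    dominance_ok: np.ndarray


@dataclass
class ScaleMatrices:
    """Centered n x m scale matrices Ha, Hd plus scaling denominators."""

    method: str
    Ha: np.ndarray
    Hd: np.ndarray
    SC_a: float
    SC_d: float
    denominator_mode: str
    scale_set: MarkerScaleSet
    ids: np.ndarray
    markers: np.ndarray


@dataclass
class OrthogonalityReport:
    """Per-marker angle between additive and dominance scale vectors."""

    markers: np.ndarray
    inner_product: np.ndarray
    norm_u: np.ndarray
    norm_v: np.ndarray
    cos_theta: np.ndarray
    theta_degrees: np.ndarray  # NaN where either norm vanishes


def _mask(scale_set: MarkerScaleSet) -> MarkerScaleSet:
    """Flag degenerate markers and zero their SC contributions in place.

    Triple values stay as the formulas give them (where defined); exclusion
    from Ha/Hd happens when the matrices are assembled.
    """
    s = scale_set
    s.additive_ok &= s.sc_a_contrib > DEGENERACY_TOL
    s.dominance_ok &= s.sc_d_contrib > DEGENERACY_TOL
    s.sc_a_contrib[~s.additive_ok] = 0.0
    s.sc_d_contrib[~s.dominance_ok] = 0.0
    return s


def _triple(aa: np.ndarray, het: np.ndarray, bb: np.ndarray) -> np.ndarray:
    return np.column_stack([aa, het, bb])


def hw_scales(f: GenotypeFrequencies) -> MarkerScaleSet:
    """Hardy-Weinberg scales: additive (2-2p, 1-2p, -2p), dominance
    (-2pq, 1-2pq, -2pq), with SC contributions 2pq and 2pq(1-2pq)."""
    p, q = f.p, f.q
    two_pq = 2.0 * p * q
    additive = _triple(2.0 - 2.0 * p, 1.0 - 2.0 * p, -2.0 * p)
    dominance = _triple(-two_pq, 1.0 - two_pq, -two_pq)
    m = f.m
    return _mask(
        MarkerScaleSet(
            method="hw",
            additive=additive,
            dominance=dominance,
            sc_a_contrib=two_pq.copy(),
            sc_d_contrib=two_pq * (1.0 - two_pq),
            additive_ok=np.ones(m, dtype=bool),
            dominance_ok=np.ones(m, dtype=bool),
        )
    )


def nohw_scales(f: GenotypeFrequencies) -> MarkerScaleSet:
    """Centering by observed genotype frequencies, no orthogonalization.

    Additive (1-D, -D, -1-D) with D = pAA - paa; dominance
    (-pAa, 1-pAa, -pAa). SC contributions are the per-marker genotypic
    variances pAA + paa - D^2 and pAa - pAa^2.
    """
    delta = f.p_AA - f.p_aa
    additive = _triple(1.0 - delta, -delta, -1.0 - delta)
    dominance = _triple(-f.p_Aa, 1.0 - f.p_Aa, -f.p_Aa)
    m = f.m
    return _mask(
        MarkerScaleSet(
            method="nohw",
            additive=additive,
            dominance=dominance,
            sc_a_contrib=f.p_AA + f.p_aa - delta**2,
            sc_d_contrib=f.p_Aa - f.p_Aa**2,
            additive_ok=np.ones(m, dtype=bool),
            dominance_ok=np.ones(m, dtype=bool),
        )
    )


def _noia_like(f: GenotypeFrequencies, method: str) -> MarkerScaleSet:
    """Shared NOIA / GSP-A construction via the Gram-Schmidt projection.

    The additive vector is kept as in ``nohw``; the dominance vector has its
    projection onto the additive vector removed, which reproduces the NOIA
    dominance triple algebraically. The dominance SC contribution is the
    expected squared length 4 pAA pAa paa / den with den = pAA + paa - D^2.
    """
    base = nohw_scales(f)
    delta = f.p_AA - f.p_aa
    den = f.p_AA + f.p_aa - delta**2
    additive_ok = den > DEGENERACY_TOL
    safe_den = np.where(additive_ok, den, 1.0)
    # projection coefficient <u, v>/<u, u> = (-pAa)(pAA - paa)/den
    coef = (-f.p_Aa) * delta / safe_den
    dominance = base.dominance - coef[:, None] * base.additive
    dominance[~additive_ok] = 0.0  # projection undefined for these markers
    sc_d = 4.0 * f.p_AA * f.p_Aa * f.p_aa / safe_den
    return _mask(
        MarkerScaleSet(
            method=method,
            additive=base.additive,
            dominance=dominance,
            sc_a_contrib=np.where(additive_ok, den, 0.0),
            sc_d_contrib=np.where(additive_ok, sc_d, 0.0),
            additive_ok=additive_ok,
            dominance_ok=additive_ok.copy(),
        )
    )


def noia_scales(f: GenotypeFrequencies) -> MarkerScaleSet:
    """Orthogonal NOIA scales; relationship scaling uses the realized trace."""
    return _noia_like(f, "noia")


def gspa_scales(f: GenotypeFrequencies) -> MarkerScaleSet:
    """Gram-Schmidt starting from the additive vector (equals NOIA scales);
    relationship scaling uses the expected trace."""
    return _noia_like(f, "gspa")


def gspd_scales(f: GenotypeFrequencies) -> MarkerScaleSet:
    """Gram-Schmidt starting from the dominance vector.

    Dominance keeps the ``nohw`` triple (-pAa, 1-pAa, -pAa) with SC
    contribution pAa(1-pAa); the additive vector becomes
    (2 paa/(1-pAa), 0, -2 pAA/(1-pAa)) with expected contribution
    4 pAA paa / (pAA + paa). Markers with pAa = 1 have no additive scale.
    """
    base = nohw_scales(f)
    one_minus_het = 1.0 - f.p_Aa
    hom_sum = f.p_AA + f.p_aa
    additive_ok = (one_minus_het > DEGENERACY_TOL) & (hom_sum > DEGENERACY_TOL)
    safe = np.where(additive_ok, one_minus_het, 1.0)
    additive = _triple(
        2.0 * f.p_aa / safe, np.zeros(f.m), -2.0 * f.p_AA / safe
    )
    additive[~additive_ok] = 0.0
    sc_a = np.where(
        additive_ok, 4.0 * f.p_AA * f.p_aa / np.where(additive_ok, hom_sum, 1.0), 0.0
    )
    return _mask(
        MarkerScaleSet(
            method="gspd",
            additive=additive,
            dominance=base.dominance,
            sc_a_contrib=sc_a,
            sc_d_contrib=base.sc_d_contrib,
            additive_ok=additive_ok,
            dominance_ok=np.ones(f.m, dtype=bool),
        )
    )


def gspn_scales(f: GenotypeFrequencies, n: int) -> MarkerScaleSet:
    """Orthonormal scales: the GSP-A basis divided by the vector norms
    sqrt(n * den) and sqrt(n * 4 pAA pAa paa / den), so every polymorphic
    marker contributes a unit-length column to Ha and Hd."""
    base = gspa_scales(f)
    norm_a = np.sqrt(n * base.sc_a_contrib)
    norm_d = np.sqrt(n * base.sc_d_contrib)
    additive_ok = base.additive_ok & (norm_a > DEGENERACY_TOL)
    dominance_ok = base.dominance_ok & (norm_d > DEGENERACY_TOL)
    additive = np.where(
        additive_ok[:, None], base.additive / np.where(additive_ok, norm_a, 1.0)[:, None], 0.0
    )
    dominance = np.where(
        dominance_ok[:, None], base.dominance / np.where(dominance_ok, norm_d, 1.0)[:, None], 0.0
    )
    # each retained marker contributes 1/n to tr(HH')/n
    unit = 1.0 / n
    return MarkerScaleSet(
        method="gspn",
        additive=additive,
        dominance=dominance,
        sc_a_contrib=np.where(additive_ok, unit, 0.0),
        sc_d_contrib=np.where(dominance_ok, unit, 0.0),
        additive_ok=additive_ok,
        dominance_ok=dominance_ok,
    )


def compute_scales(
    f: GenotypeFrequencies, method: str, n: int | None = None
) -> MarkerScaleSet:
    """Dispatch to the requested parameterization."""
    method = normalize_method(method)
    if method == "gspn":
        if n is None:
            raise ValueError("gspn scales require the individual count n")
        return gspn_scales(f, n)
    return {
        "hw": hw_scales,
        "nohw": nohw_scales,
        "noia": noia_scales,
        "gspa": gspa_scales,
        "gspd": gspd_scales,
    }[method](f)


def build_scale_matrices(
    g: GenotypeMatrix,
    method: str,
    f: GenotypeFrequencies | None = None,
    denominator: str | None = None,
) -> ScaleMatrices:
    """Assemble the centered n x m matrices Ha, Hd and their denominators.

    Entries come from each marker's genotype triple; missing genotypes get 0
    (mean imputation after centering). The denominator is the sum of expected
    per-marker contributions or the realized trace tr(HH')/n, fixed per
    method unless overridden.
    """
    method = normalize_method(method)
    if f is None:
        f = compute_frequencies(g)
    s = compute_scales(f, method, n=g.n)
    if not s.additive_ok.any() and not s.dominance_ok.any():
        raise ValueError("all markers are degenerate for method " + method)
    # genotype code 2/1/0 -> triple column 0/1/2; missing -> 0 afterwards
    col = 2 - np.clip(g.codes, 0, 2)
    rows = np.arange(g.m)[None, :]
    Ha = s.additive[rows, col]
    Hd = s.dominance[rows, col]
    Ha[:, ~s.additive_ok] = 0.0  # degenerate markers do not contribute
    Hd[:, ~s.dominance_ok] = 0.0
    miss = g.missing_mask
    if miss.any():
        Ha[miss] = 0.0
        Hd[miss] = 0.0
    mode = denominator or DENOMINATOR_MODE[method]
    if mode == "expected_sum":
        sc_a = float(s.sc_a_contrib.sum())
        sc_d = float(s.sc_d_contrib.sum())
    elif mode == "realized_trace":
        sc_a = float((Ha**2).sum() / g.n)
        sc_d = float((Hd**2).sum() / g.n)
    else:
        raise ValueError(f"unknown denominator mode {mode!r}")
    return ScaleMatrices(
        method=method,
        Ha=Ha,
        Hd=Hd,
        SC_a=sc_a,
        SC_d=sc_d,
        denominator_mode=mode,
        scale_set=s,
        ids=g.ids,
        markers=g.markers,
    )


def marker_angle(f: GenotypeFrequencies, n: int) -> OrthogonalityReport:
    """Angle between each marker's additive and dominance scale vectors
    (frequency-centered, pre-orthogonalization).

    inner = n(-pAa)(pAA - paa); ||u|| = sqrt(n[pAA + paa - (pAA - paa)^2]);
    ||v|| = sqrt(n pAa(1 - pAa)). The angle is 90 degrees exactly when the
    two homozygotes have equal frequency or there are no heterozygotes
    (degenerate, reported as NaN).
    """
    delta = f.p_AA - f.p_aa
    inner = n * (-f.p_Aa) * delta
    norm_u = np.sqrt(n * np.maximum(f.p_AA + f.p_aa - delta**2, 0.0))
    norm_v = np.sqrt(n * np.maximum(f.p_Aa * (1.0 - f.p_Aa), 0.0))
    ok = (norm_u > 0) & (norm_v > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos = np.where(ok, inner / np.where(ok, norm_u * norm_v, 1.0), np.nan)
    cos = np.clip(cos, -1.0, 1.0)
    theta = np.degrees(np.arccos(cos))
    return OrthogonalityReport(
        markers=f.markers,
        inner_product=inner,
        norm_u=norm_u,
        norm_v=norm_v,
        cos_theta=cos,
        theta_degrees=theta,
    )


def verify_orthogonality(
    s: MarkerScaleSet, f: GenotypeFrequencies, tol: float = 1e-10
) -> dict:
    """Frequency-weighted centering and orthogonality residuals per marker.

    Returns the three sums sum_g p_g u_g, sum_g p_g v_g, and
    sum_g p_g u_g v_g for each marker, plus a certification flag: a method
    is orthogonal when the largest absolute cross residual is below ``tol``.
    """
    w = np.column_stack([f.p_AA, f.p_Aa, f.p_aa])
    additive_residual = (w * s.additive).sum(axis=1)
    dominance_residual = (w * s.dominance).sum(axis=1)
    cross_residual = (w * s.additive * s.dominance).sum(axis=1)
    return {
        "additive_residual": additive_residual,
        "dominance_residual": dominance_residual,
        "cross_residual": cross_residual,
        "orthogonal": bool(np.abs(cross_residual).max(initial=0.0) < tol),
    }


class MarkerScales(BaseEstimator, TransformerMixin):
    """Transformer mapping genotype codes to centered marker scales.

    Parameters
    ----------
    method : str
        One of ``hw, nohw, noia, gspa, gspd, gspn``.
    component : str
        ``"additive"`` returns Ha, ``"dominance"`` returns Hd.

    After ``fit`` the genotype frequencies and scale triples of the training
    panel are stored and reused to transform new individuals.
    """

    def __init__(self, method: str = "noia", component: str = "additive"):
        self.method = method
        self.component = component

    def _codes(self, X) -> np.ndarray:
        if isinstance(X, GenotypeMatrix):
            return X.codes
        X = np.asarray(X)
        return X.astype(np.int16)

    def fit(self, X, y=None):
        codes = self._codes(X)
        g = X if isinstance(X, GenotypeMatrix) else GenotypeMatrix(
            np.arange(codes.shape[0]), np.arange(codes.shape[1]), codes
        )
        self.n_features_in_ = g.m
        self.frequencies_ = compute_frequencies(g)
        self.scale_set_ = compute_scales(self.frequencies_, self.method, n=g.n)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "scale_set_"):
            raise RuntimeError("MarkerScales is not fitted")
        codes = self._codes(X)
        if codes.shape[1] != self.n_features_in_:
            raise ValueError("marker count differs from the fitted panel")
        if self.component == "additive":
            triples, ok = self.scale_set_.additive, self.scale_set_.additive_ok
        elif self.component == "dominance":
            triples, ok = self.scale_set_.dominance, self.scale_set_.dominance_ok
        else:
            raise ValueError(f"unknown component {self.component!r}")
        col = 2 - np.clip(codes, 0, 2)
        H = triples[np.arange(codes.shape[1])[None, :], col]
        H[:, ~ok] = 0.0
        H[codes == MISSING] = 0.0
        return H
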