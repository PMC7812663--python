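"""Additive (G) and dominance (D) relationship matrices, their summaries,
and the Kullback-Leibler divergence between two relationship matrices."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigvalsh
from sklearn.base import BaseEstimator, TransformerMixin

from .genotypes import GenotypeMatrix, compute_frequencies
from .scales import (
    DENOMINATOR_MODE,
    MarkerScales,
    ScaleMatrices,
    build_scale_matrices,
    normalize_method,
)

__all__ = [
    "RelationshipMatrix",
    "MatrixSummary",
    "KLDivergence",
    "GenomicRelationship",
    "build_grm",
    "matrix_summary",
    "kl_divergence",
]


@dataclass
class RelationshipMatrix:
    """Symmetric n x n relationship matrix with its construction metadata."""

    kind: str  # additive | dominance
    method: str
    values: np.ndarray
    ids: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class MatrixSummary:
    avg_diagonal: float
    avg_off_diagonal: float
    min_eigenvalue: float
    max_eigenvalue: float


@dataclass
class KLDivergence:
    value: float  # nats
    direction: tuple[str, str]
    ridge_used: float


def build_grm(s: ScaleMatrices, kind: str = "additive") -> RelationshipMatrix:
    """G = Ha Ha'/SC_a (or D = Hd Hd'/SC_d) from assembled scale matrices."""
    if kind == "additive":
        H, sc = s.Ha, s.SC_a
    elif kind == "dominance":
        H, sc = s.Hd, s.SC_d
    else:
        raise ValueError(f"unknown kind {kind!r}")
    if sc <= 1e-12:
        raise ValueError(
            f"{kind} scaling denominator is zero for method {s.method} "
            "(no polymorphic markers contribute)"
        )
    values = (H @ H.T) / sc
    values = 0.5 * (values + values.T)  # enforce exact symmetry
    return RelationshipMatrix(kind=kind, method=s.method, values=values, ids=s.ids)


def matrix_summary(r: RelationshipMatrix | np.ndarray) -> MatrixSummary:
    """Average diagonal/off-diagonal elements and the eigenvalue range."""
    v = r.values if isinstance(r, RelationshipMatrix) else np.asarray(r)
    n = v.shape[0]
    if n < 2:
        raise ValueError("summary requires n >= 2")
    trace = float(np.trace(v))
    total = float(v.sum())
    eig = eigvalsh(v)
    # tiny negative rounding is reported as zero
    eig = np.where((eig < 0) & (eig > -1e-8), 0.0, eig)
    return MatrixSummary(
        avg_diagonal=trace / n,
        avg_off_diagonal=(total - trace) / (n * n - n),
        min_eigenvalue=float(eig.min()),
        max_eigenvalue=float(eig.max()),
    )


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, RelationshipMatrix) else np.asarray(x, dtype=float)


def kl_divergence(
    P,
    Q,
    ridge: float = 1e-6,
    mu_p: np.ndarray | None = None,
    mu_q: np.ndarray | None = None,
) -> KLDivergence:
    """Kullback-Leibler divergence D_KL(P || Q) between two zero-mean
    multivariate normal distributions with the given covariance matrices.

    D_KL = 0.5 [trace(Q^-1 P) + (mu_Q - mu_P)' Q^-1 (mu_Q - mu_P) - n
                + ln(|Q|/|P|)]

    Both matrices get ``ridge`` added to the diagonal before factorization
    (Gram matrices built from m < n markers are singular). Means default to
    zero vectors, the natural choice for centered genetic effects.
    """
    Pv, Qv = _values(P), _values(Q)
    if Pv.shape != Qv.shape or Pv.shape[0] != Pv.shape[1]:
        raise ValueError("P and Q must be square matrices of the same size")
    n = Pv.shape[0]
    eye = np.eye(n)
    Pr = Pv + ridge * eye
    Qr = Qv + ridge * eye
    try:
        cq = cho_factor(Qr, lower=True)
        cp = cho_factor(Pr, lower=True)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "matrix not positive definite after ridging; increase ridge"
        ) from err
    logdet_q = 2.0 * float(np.log(np.diag(cq[0])).sum())
    logdet_p = 2.0 * float(np.log(np.diag(cp[0])).sum())
    trace_term = float(np.trace(cho_solve(cq, Pr)))
    quad = 0.0
    if mu_p is not None or mu_q is not None:
        mu_p = np.zeros(n) if mu_p is None else np.asarray(mu_p, dtype=float)
        mu_q = np.zeros(n) if mu_q is None else np.asarray(mu_q, dtype=float)
        diff = mu_q - mu_p
        quad = float(diff @ cho_solve(cq, diff))
    value = 0.5 * (trace_term + quad - n + logdet_q - logdet_p)
    name = lambda x: x.method if isinstance(x, RelationshipMatrix) else "P"
    return KLDivergence(
        value=value,
        direction=(name(P), name(Q) if isinstance(Q, RelationshipMatrix) else "Q"),
        ridge_used=ridge,
    )


class GenomicRelationship(BaseEstimator, TransformerMixin):
    """Kernel-style transformer computing genomic relationships.

    ``fit(X)`` learns genotype frequencies, scale triples and the scaling
    denominator from a reference panel of 0/1/2 codes; ``transform(X)``
    returns the n_X x n_fit matrix of relationships between new individuals
    and the fitted panel, so ``fit_transform(X)`` is the usual square G or D.

    Parameters
    ----------
    method : str
        Parameterization, one of ``hw, nohw, noia, gspa, gspd, gspn``.
    kind : str
        ``"additive"`` (G) or ``"dominance"`` (D).
    denominator : str or None
        Override of the per-method scaling convention
        (``expected_sum`` or ``realized_trace``).
    """

    def __init__(
        self,
        method: str = "noia",
        kind: str = "additive",
        denominator: str | None = None,
    ):
        self.method = method
        self.kind = kind
        self.denominator = denominator

    def fit(self, X, y=None):
        g = X if isinstance(X, GenotypeMatrix) else GenotypeMatrix(
            np.arange(np.asarray(X).shape[0]),
            np.arange(np.asarray(X).shape[1]),
            np.asarray(X),
        )
        self.n_features_in_ = g.m
        self.frequencies_ = compute_frequencies(g)
        self.scale_matrices_ = build_scale_matrices(
            g, self.method, f=self.frequencies_, denominator=self.denominator
        )
        component = "additive" if self.kind == "additive" else "dominance"
        self._scaler = MarkerScales(method=self.method, component=component)
        self._scaler.n_features_in_ = g.m
        self._scaler.frequencies_ = self.frequencies_
        self._scaler.scale_set_ = self.scale_matrices_.scale_set
        self.H_fit_ = (
            self.scale_matrices_.Ha if self.kind == "additive" else self.scale_matrices_.Hd
        )
        self.sc_ = (
            self.scale_matrices_.SC_a if self.kind == "additive" else self.scale_matrices_.SC_d
        )
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "H_fit_"):
            raise RuntimeError("GenomicRelationship is not fitted")
        H_new = self._scaler.transform(
            X.codes if isinstance(X, GenotypeMatrix) else np.asarray(X)
        )
        return (H_new @ self.H_fit_.T) / self.sc_

    def relationship_matrix(self, X) -> RelationshipMatrix:
        """Fit on ``X`` and return the square matrix with metadata."""
        self.fit(X)
        return build_grm(self.scale_matrices_, kind=self.kind)


def _method_mode(method: str) -> str:
    return DENOMINATOR_MODE[normalize_method(method)]
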