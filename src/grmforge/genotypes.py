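"""Genotype matrices, genotype/allele frequencies, and the exact HWE test.

Genotypes are coded as copies of the reference allele A: 2 = AA, 1 = Aa,
0 = aa. Missing genotypes are carried as a mask; all frequency computations
use pairwise-complete (per-marker) denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

MISSING = -1

__all__ = [
    "GenotypeMatrix",
    "GenotypeFrequencies",
    "HweTestResult",
    "read_genotypes",
    "compute_frequencies",
    "hwe_exact_test",
    "hwe_test",
    "heterozygote_excess",
]


@dataclass
class GenotypeMatrix:
    """n individuals x m biallelic markers, codes in {0, 1, 2, MISSING}."""

    ids: np.ndarray
    markers: np.ndarray
    codes: np.ndarray  # int array, MISSING (-1) marks missing cells

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.markers = np.asarray(self.markers, dtype=object)
        self.codes = np.asarray(self.codes, dtype=np.int16)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D array")
        n, m = self.codes.shape
        if n < 1 or m < 1:
            raise ValueError("need at least one individual and one marker")
        if len(self.ids) != n or len(self.markers) != m:
            raise ValueError("ids/markers lengths do not match codes shape")
        for name, vals in (("individual", self.ids), ("marker", self.markers)):
            if len(set(map(str, vals))) != len(vals):
                raise ValueError(f"duplicate {name} identifiers")
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {self.codes[i, j]} for individual "
                f"{self.ids[i]!r}, marker {self.markers[j]!r}"
            )

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def m(self) -> int:
        return self.codes.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.codes == MISSING


@dataclass
class GenotypeFrequencies:
    """Per-marker genotype counts and frequencies (pairwise-complete)."""

    markers: np.ndarray
    n_AA: np.ndarray
    n_Aa: np.ndarray
    n_aa: np.ndarray
    n_obs: np.ndarray = field(init=False)
    p_AA: np.ndarray = field(init=False)
    p_Aa: np.ndarray = field(init=False)
    p_aa: np.ndarray = field(init=False)
    p: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.markers = np.asarray(self.markers, dtype=object)
        # float counts allow exact theoretical frequencies (from_proportions)
        self.n_AA = np.asarray(self.n_AA, dtype=float)
        self.n_Aa = np.asarray(self.n_Aa, dtype=float)
        self.n_aa = np.asarray(self.n_aa, dtype=float)
        self.n_obs = self.n_AA + self.n_Aa + self.n_aa
        if (self.n_obs == 0).any():
            empty = self.markers[self.n_obs == 0]
            raise ValueError(f"markers with no observed genotypes: {list(empty)}")
        self.p_AA = self.n_AA / self.n_obs
        self.p_Aa = self.n_Aa / self.n_obs
        self.p_aa = self.n_aa / self.n_obs
        # allele-A frequency: p = pAA + pAa/2
        self.p = self.p_AA + 0.5 * self.p_Aa

    @property
    def q(self) -> np.ndarray:
        return 1.0 - self.p

    @property
    def m(self) -> int:
        return len(self.markers)

    @classmethod
    def from_proportions(cls, p_AA, p_Aa, p_aa, n_obs=1, markers=None):
        """Build from genotype proportions (each simplex triple scaled by
        ``n_obs``); handy for theoretical frequencies such as (p^2, 2pq, q^2)."""
        p_AA = np.atleast_1d(np.asarray(p_AA, dtype=float))
        p_Aa = np.atleast_1d(np.asarray(p_Aa, dtype=float))
        p_aa = np.atleast_1d(np.asarray(p_aa, dtype=float))
        total = p_AA + p_Aa + p_aa
        if np.any(np.abs(total - 1.0) > 1e-9) or np.any(
            (p_AA < 0) | (p_Aa < 0) | (p_aa < 0)
        ):
            raise ValueError("proportions must be non-negative and sum to 1")
        if markers is None:
            markers = np.array([f"snp{j + 1:05d}" for j in range(len(p_AA))], dtype=object)
        return cls(
            markers=markers, n_AA=p_AA * n_obs, n_Aa=p_Aa * n_obs, n_aa=p_aa * n_obs
        )


@dataclass
class HweTestResult:
    """Per-marker exact HWE p-values and heterozygote excess."""

    markers: np.ndarray
    p_value: np.ndarray
    het_excess: np.ndarray  # NaN where 2pq = 0


def _parse_codes(raw: pd.DataFrame, missing_token: str) -> np.ndarray:
    cells = raw.to_numpy(dtype=str)
    cells = np.char.strip(cells.astype(str))
    codes = np.full(cells.shape, MISSING, dtype=np.int16)
    known = np.zeros(cells.shape, dtype=bool)
    for tok, val in (("0", 0), ("1", 1), ("2", 2), (missing_token, MISSING)):
        hit = cells == tok
        codes[hit] = val
        known |= hit
    if not known.all():
        i, j = np.argwhere(~known)[0]
        raise ValueError(
            f"unparseable genotype cell {cells[i, j]!r} at individual "
            f"{raw.index[i]!r}, marker {raw.columns[j]!r} "
            f"(expected 0/1/2 or {missing_token!r})"
        )
    return codes


def read_genotypes(
    path, format: str = "matrix012", missing_token: str = "NA"
) -> GenotypeMatrix:
    """Read a genotype matrix from a TSV (``matrix012``) or a PLINK
    ``.raw``-dialect file (``plink_raw``).

    matrix012: header row = marker ids, first column = individual id, cells
    in {0, 1, 2, missing_token}. plink_raw: whitespace-separated with columns
    FID IID PAT MAT SEX PHENOTYPE followed by one allele-count column per
    marker; only IID and the marker columns are consumed.
    """
    na_opts = dict(dtype=str, keep_default_na=False, na_values=[])
    if format == "matrix012":
        df = pd.read_csv(path, sep="\t", index_col=0, **na_opts)
    elif format == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", **na_opts)
        meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        missing_cols = [c for c in meta if c not in df.columns]
        if missing_cols:
            raise ValueError(f"plink_raw file lacks columns: {missing_cols}")
        df = df.set_index("IID").drop(columns=[c for c in meta if c != "IID"])
    else:
        raise ValueError(f"unknown genotype format: {format!r}")
    codes = _parse_codes(df, missing_token)
    return GenotypeMatrix(df.index.to_numpy(), df.columns.to_numpy(), codes)


def compute_frequencies(g: GenotypeMatrix) -> GenotypeFrequencies:
    """Genotype and allele frequencies per marker over non-missing individuals."""
    return GenotypeFrequencies(
        markers=g.markers,
        n_AA=(g.codes == 2).sum(axis=0),
        n_Aa=(g.codes == 1).sum(axis=0),
        n_aa=(g.codes == 0).sum(axis=0),
    )


def _hwe_log_probs(n_het_obs: int, n_A: int, n_a: int) -> tuple[np.ndarray, int]:
    """Conditional log-probabilities of every feasible heterozygote count
    given the allele counts, and the index of the observed count."""
    n = (n_A + n_a) // 2
    rare = min(n_A, n_a)
    ks = np.arange(rare % 2, rare + 1, 2)
    n_AA = (n_A - ks) // 2
    n_aa = (n_a - ks) // 2
    logp = (
        gammaln(n + 1)
        - gammaln(n_AA + 1)
        - gammaln(ks + 1)
        - gammaln(n_aa + 1)
        + ks * np.log(2.0)
        - (gammaln(2 * n + 1) - gammaln(n_A + 1) - gammaln(n_a + 1))
    )
    logp -= logsumexp(logp)  # exact normalization guards rounding
    (obs_idx,) = np.nonzero(ks == n_het_obs)
    return logp, int(obs_idx[0])


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact HWE test by full enumeration of heterozygote counts
    conditional on the allele counts.

    The p-value is the sum of conditional probabilities of all heterozygote
    configurations no more probable than the observed one (ties included).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    if n_AA + n_Aa + n_aa < 1:
        raise ValueError("at least one observed genotype is required")
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    logp, obs = _hwe_log_probs(n_Aa, n_A, n_a)
    probs = np.exp(logp)
    p = probs[probs <= probs[obs] * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_test(f: GenotypeFrequencies) -> HweTestResult:
    """Exact HWE test and heterozygote excess for every marker."""
    counts = np.round(np.column_stack([f.n_AA, f.n_Aa, f.n_aa])).astype(int)
    if np.abs(counts - np.column_stack([f.n_AA, f.n_Aa, f.n_aa])).max() > 1e-6:
        raise ValueError("the exact HWE test requires integer genotype counts")
    pvals = np.array([hwe_exact_test(a, h, b) for a, h, b in counts])
    excess, _ = heterozygote_excess(f)
    return HweTestResult(markers=f.markers, p_value=pvals, het_excess=excess)


def heterozygote_excess(f: GenotypeFrequencies) -> tuple[np.ndarray, float]:
    """Relative excess of heterozygotes, (pAa - 2pq)/(2pq), per marker.

    Markers with 2pq = 0 are excluded from the mean and reported as NaN.
    Returns ``(per_marker, mean)``; the mean is NaN when no marker qualifies.
    """
    two_pq = 2.0 * f.p * f.q
    with np.errstate(divide="ignore", invalid="ignore"):
        excess = np.where(two_pq > 0, (f.p_Aa - two_pq) / two_pq, np.nan)
    ok = np.isfinite(excess)
    mean = float(excess[ok].mean()) if ok.any() else float("nan")
    return excess, mean
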