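"""Synthetic genotype panels with controllable Hardy-Weinberg departure and
phenotypes under the additive-dominance genotypic model.

Two genotype modes are provided. ``inbreeding_f`` draws each marker's
genotypes from (p^2 + Fpq, 2pq(1-F), q^2 + Fpq); a negative F produces the
heterozygote excess typical of crosses between divergent lines. ``f1_cross``
emulates an F1 between two parental pools with marker frequencies p1 and p2,
giving genotype probabilities (p1 p2, p1 q2 + p2 q1, q1 q2); when the pools
have diverged frequencies this yields a genome-wide heterozygote excess, the
crossbred signature.

Phenotypes follow y_i = mu + trial + sum_j z_ij a_j + sum_j s_ij d_j + e_i
with z in {1, 0, -1} and s in {0, 1, 0} for genotypes AA, Aa, aa. Marker
effects are drawn i.i.d. normal and rescaled so the realized sample
variances of the additive and dominance genetic values match the requested
targets exactly, giving recovery tests a well-defined truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "SimulationSpec",
    "TraitSpec",
    "simulate_genotypes",
    "simulate_phenotypes",
]


@dataclass
class SimulationSpec:
    """Genotype-panel settings; ``freq_law`` is ``("uniform", lo, hi)`` or
    ``("fixed", p)``."""

    n: int = 903
    m: int = 2000
    mode: str = "f1_cross"  # or "inbreeding_f"
    freq_law: tuple = ("uniform", 0.1, 0.9)
    freq_law2: tuple | None = None  # second parental pool (f1_cross)
    F: float = 0.0
    f_jitter: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0


@dataclass
class TraitSpec:
    mu: float = 0.0
    sigma2_a: float = 1.0
    sigma2_d: float = 0.5
    sigma2_e: float = 1.0
    n_trials: int = 1
    trial_effects: tuple | None = None
    seed: int = 0


def _draw_freqs(rng: np.random.Generator, law: tuple, m: int) -> np.ndarray:
    kind = law[0]
    if kind == "uniform":
        lo, hi = float(law[1]), float(law[2])
        return rng.uniform(lo, hi, size=m)
    if kind == "fixed":
        return np.full(m, float(law[1]))
    raise ValueError(f"unknown allele-frequency law {law!r}")


def simulate_genotypes(spec: SimulationSpec | None = None, **kwargs) -> GenotypeMatrix:
    """Draw a genotype panel; deterministic given the seed.

    Accepts a :class:`SimulationSpec` or its fields as keyword arguments.
    Infeasible (p, F) pairs (genotype probability below zero) trigger a
    redraw of that marker's allele frequency.
    """
    if spec is None:
        spec = SimulationSpec(**kwargs)
    elif kwargs:
        raise TypeError("pass either a SimulationSpec or keyword fields, not both")
    if not 0.0 <= spec.missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    ss = np.random.SeedSequence(spec.seed)
    rng_freq, rng_geno, rng_miss = (np.random.default_rng(s) for s in ss.spawn(3))

    m, n = spec.m, spec.n
    if spec.mode == "inbreeding_f":
        F = np.full(m, spec.F)
        if spec.f_jitter > 0:
            F = F + rng_freq.normal(0.0, spec.f_jitter, size=m)
        p = _draw_freqs(rng_freq, spec.freq_law, m)
        q = 1.0 - p
        for _ in range(100):
            pAA = p * p + F * p * q
            pAa = 2.0 * p * q * (1.0 - F)
            paa = q * q + F * p * q
            bad = (pAA < 0) | (pAa < 0) | (paa < 0)
            if not bad.any():
                break
            p[bad] = _draw_freqs(rng_freq, spec.freq_law, int(bad.sum()))
            q = 1.0 - p
        else:
            raise ValueError("could not find feasible allele frequencies for F")
        probs = np.stack([paa, pAa, pAA], axis=1)  # code order 0,1,2
    elif spec.mode == "f1_cross":
        p1 = _draw_freqs(rng_freq, spec.freq_law, m)
        p2 = _draw_freqs(rng_freq, spec.freq_law2 or spec.freq_law, m)
        q1, q2 = 1.0 - p1, 1.0 - p2
        probs = np.stack([q1 * q2, p1 * q2 + p2 * q1, p1 * p2], axis=1)
    else:
        raise ValueError(f"unknown simulation mode {spec.mode!r}")

    # inverse-CDF draw per marker column
    u = rng_geno.random((n, m))
    cum = np.cumsum(probs, axis=1)  # (m, 3)
    codes = (u[..., None] > cum[None, :, :]).sum(axis=2).astype(np.int16)
    if spec.missing_rate > 0:
        codes[rng_miss.random((n, m)) < spec.missing_rate] = MISSING
    ids = np.array([f"ind{i + 1:05d}" for i in range(n)], dtype=object)
    markers = np.array([f"snp{j + 1:05d}" for j in range(m)], dtype=object)
    return GenotypeMatrix(ids=ids, markers=markers, codes=codes)


def _rescaled(values: np.ndarray, target: float) -> np.ndarray:
    """Scale a vector so its sample variance (ddof=0) equals ``target``."""
    v = float(np.var(values))
    if target <= 0 or v <= 0:
        return np.zeros_like(values)
    return values * np.sqrt(target / v)


def simulate_phenotypes(
    g: GenotypeMatrix, spec: TraitSpec | None = None, **kwargs
) -> tuple[pd.DataFrame, dict]:
    """Simulate trait records for a genotype panel.

    Returns a table (id, trial, y) and a truth record with the marker
    effects, genetic values, trial effects and realized variance components.
    Missing genotypes contribute zero to both genetic sums.
    """
    if spec is None:
        spec = TraitSpec(**kwargs)
    elif kwargs:
        raise TypeError("pass either a TraitSpec or keyword fields, not both")
    for v in (spec.sigma2_a, spec.sigma2_d, spec.sigma2_e):
        if not np.isfinite(v) or v < 0:
            raise ValueError("variance targets must be finite and non-negative")
    ss = np.random.SeedSequence(spec.seed)
    rng_eff, rng_noise, rng_trial = (np.random.default_rng(s) for s in ss.spawn(3))

    codes = g.codes
    observed = codes != MISSING
    z = np.where(observed, codes.astype(float) - 1.0, 0.0)  # AA=1, Aa=0, aa=-1
    s_mat = (codes == 1).astype(float)

    a = rng_eff.standard_normal(g.m)
    d = rng_eff.standard_normal(g.m)
    bv = _rescaled(z @ a, spec.sigma2_a)
    dv = _rescaled(s_mat @ d, spec.sigma2_d)
    e = rng_noise.normal(0.0, np.sqrt(spec.sigma2_e), size=g.n) if spec.sigma2_e > 0 else np.zeros(g.n)

    if spec.n_trials > 1:
        effects = (
            np.asarray(spec.trial_effects, dtype=float)
            if spec.trial_effects is not None
            else rng_trial.normal(0.0, 1.0, size=spec.n_trials)
        )
        if len(effects) != spec.n_trials:
            raise ValueError("trial_effects length must equal n_trials")
        trial = np.arange(g.n) % spec.n_trials
    else:
        effects = np.zeros(1)
        trial = np.zeros(g.n, dtype=int)

    y = spec.mu + effects[trial] + bv + dv + e
    df = pd.DataFrame(
        {"id": g.ids, "trial": [f"trial{t + 1}" for t in trial], "y": y}
    )
    truth = {
        "additive_effects": a * (0.0 if np.var(z @ a) == 0 or spec.sigma2_a <= 0 else np.sqrt(spec.sigma2_a / np.var(z @ a))),
        "dominance_effects": d * (0.0 if np.var(s_mat @ d) == 0 or spec.sigma2_d <= 0 else np.sqrt(spec.sigma2_d / np.var(s_mat @ d))),
        "breeding_values": bv,
        "dominance_values": dv,
        "residuals": e,
        "trial_effects": effects,
        "realized_sigma2_a": float(np.var(bv)),
        "realized_sigma2_d": float(np.var(dv)),
        "realized_sigma2_e": float(np.var(e)),
    }
    return df, truth
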