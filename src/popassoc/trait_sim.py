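"""Quantitative trait simulation with exact heritability calibration.

The trait is y = 1 a + X_C' b + Z' eta + eps: an intercept, additive causal
effects over a causal locus set C, optional environment group effects, and
iid Gaussian residuals with variance sig_eps^2 = 1 - h^2 - sum(sig_eta^2).

Two coefficient models are supported.  FES (fixed effect sizes) sets
b_i proportional to 1 / sqrt(v_i) with random signs, where v_i = p_i (1 - p_i)
is the allele variance, so every causal locus contributes the same effect
size 2 v_i b_i^2; this mimics the inverse frequency-effect relationship seen
under selection.  RC (random coefficients) draws b_i ~ Normal(0, 1)
independent of frequency.  Both are rescaled so the genetic variance sums
exactly to h^2 when ancestral frequencies are known; with estimated
frequencies the calibration holds in expectation through a kinship-based
bias correction of the allele variances and of the intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from popassoc._util import as_rng
from popassoc.data_io import GenotypeMatrix


def num_causal(n: int, h2: float) -> int:
    """Causal locus count heuristic m1 = round(n h^2 / 8), minimum 1.

    Rounding is round-half-even; the heuristic balances per-locus power
    across sample sizes and heritabilities.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must lie in (0, 1)")
    return max(1, int(np.round(n * h2 / 8.0)))


def make_env_groups(n: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Contiguous environment groups g = ceil(j k / n) for j = 1..n.

    Returns (group labels 1..k, indicator design Z of shape (k, n)).
    """
    if not 1 <= k <= n:
        raise ValueError("need 1 <= k <= n")
    j = np.arange(1, n + 1)
    groups = np.ceil(j * k / n).astype(int)
    Z = (groups[None, :] == np.arange(1, k + 1)[:, None]).astype(float)
    return groups, Z


def construct_coefficients(
    freqs: np.ndarray | GenotypeMatrix,
    causal: np.ndarray,
    model: str = "fes",
    h2: float = 0.8,
    mean_kinship: float | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, float]:
    """Causal coefficients beta (over ``causal``) and intercept alpha.

    ``freqs`` is either the vector of true ancestral frequencies (known-p
    path) or a GenotypeMatrix, in which case frequencies are estimated from
    the sample and ``mean_kinship`` (mean bias-corrected kinship over all
    n^2 pairs) is required to de-bias the allele variances, via
    v_hat = p_hat (1 - p_hat) / (1 - mean_kinship), and the intercept uses
    the product-of-sums form alpha = -(2 / m1) (sum p_hat) (sum beta).
    """
    rng = as_rng(rng)
    causal = np.asarray(causal, dtype=int)
    if causal.size == 0:
        raise ValueError("causal set must be non-empty")
    known_p = not isinstance(freqs, GenotypeMatrix)
    if known_p:
        p = np.asarray(freqs, dtype=float)[causal]
        v = p * (1.0 - p)
    else:
        if mean_kinship is None:
            raise ValueError(
                "mean_kinship is required with estimated frequencies"
            )
        p = freqs.allele_freq()[causal]
        v = p * (1.0 - p) / (1.0 - mean_kinship)
    if np.any(v <= 0.0):
        raise ValueError("causal locus with zero allele variance")

    model = model.lower()
    if model == "fes":
        beta = 1.0 / np.sqrt(2.0 * v)
        beta *= np.where(rng.random(causal.size) < 0.5, -1.0, 1.0)
    elif model == "rc":
        beta = rng.standard_normal(causal.size)
    else:
        raise ValueError(f"unknown coefficient model {model!r}")

    sigma0 = np.sqrt(np.sum(2.0 * v * beta**2))
    beta = beta * (np.sqrt(h2) / sigma0)

    if known_p:
        alpha = -float(np.sum(2.0 * p * beta))
    else:
        m1 = causal.size
        alpha = -float(2.0 / m1 * p.sum() * beta.sum())
    return beta, alpha


@dataclass
class TraitModel:
    """Fully specified trait generator for one genotype dataset."""

    causal: np.ndarray
    beta: np.ndarray
    alpha: float
    h2: float
    env_designs: list[np.ndarray] = field(default_factory=list)  # each (k_i, n)
    env_vars: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.causal = np.asarray(self.causal, dtype=int)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.causal.shape != self.beta.shape:
            raise ValueError("causal and beta must align")
        if len(self.env_designs) != len(self.env_vars):
            raise ValueError("one variance per environment design")
        if self.sigma_eps2 < 0:
            raise ValueError(
                f"infeasible variance partition: h2={self.h2}, "
                f"env={sum(self.env_vars)}"
            )

    @property
    def sigma_eps2(self) -> float:
        return 1.0 - self.h2 - float(sum(self.env_vars))


@dataclass
class TraitReplicate:
    """One realized trait: y and its components."""

    y: np.ndarray
    genetic: np.ndarray
    environment: np.ndarray
    residual: np.ndarray
    eta: list[np.ndarray]


def simulate_trait(
    G: GenotypeMatrix,
    model: TraitModel,
    rng: np.random.Generator | int | None = None,
) -> TraitReplicate:
    """Assemble y = 1 a + X_C' b + Z' eta + eps with fresh eta and eps."""
    rng = as_rng(rng)
    n = G.n
    genetic = G.dosages[model.causal].astype(float).T @ model.beta
    environment = np.zeros(n)
    etas: list[np.ndarray] = []
    for Z, var in zip(model.env_designs, model.env_vars):
        eta = rng.normal(0.0, np.sqrt(var), size=Z.shape[0])
        environment += Z.T @ eta
        etas.append(eta)
    residual = rng.normal(0.0, np.sqrt(model.sigma_eps2), size=n)
    y = model.alpha + genetic + environment + residual
    return TraitReplicate(
        y=y, genetic=genetic, environment=environment,
        residual=residual, eta=etas,
    )


def simulate_trait_replicate(
    G: GenotypeMatrix,
    h2: float,
    p_anc: np.ndarray | None = None,
    model: str = "fes",
    m1: int | None = None,
    env_group_counts: list[int] | None = None,
    env_vars: list[float] | None = None,
    mean_kinship: float | None = None,
    maf_min: float = 0.01,
    rng: np.random.Generator | int | None = None,
) -> tuple[TraitModel, TraitReplicate]:
    """Draw a fresh causal set, coefficients, and one trait realization.

    The causal set is sampled uniformly from loci with sample MAF >=
    ``maf_min`` (rare causal variants are not discoverable at these sample
    sizes).  Known ancestral frequencies ``p_anc`` give exact heritability
    calibration; otherwise estimated frequencies with the kinship-based
    correction are used.
    """
    rng = as_rng(rng)
    if m1 is None:
        m1 = num_causal(G.n, h2)
    eligible = np.flatnonzero(G.maf() >= maf_min)
    if eligible.size < m1:
        raise ValueError(
            f"only {eligible.size} loci with MAF >= {maf_min}, need {m1}"
        )
    causal = np.sort(rng.choice(eligible, size=m1, replace=False))
    freqs = p_anc if p_anc is not None else G
    beta, alpha = construct_coefficients(
        freqs, causal, model=model, h2=h2, mean_kinship=mean_kinship, rng=rng
    )
    env_designs = []
    env_group_counts = env_group_counts or []
    env_vars = env_vars or []
    for k in env_group_counts:
        _, Z = make_env_groups(G.n, k)
        env_designs.append(Z)
    tm = TraitModel(
        causal=causal, beta=beta, alpha=alpha, h2=h2,
        env_designs=env_designs, env_vars=list(env_vars),
    )
    return tm, simulate_trait(G, tm, rng=rng)
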