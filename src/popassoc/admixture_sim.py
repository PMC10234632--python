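"""Genotype simulation from a 1D-geography admixture model.

K intermediate subpopulations sit at coordinates 1..K on a line; subpopulation
u has total inbreeding f_u = u * tau (linearly increasing differentiation).
Each individual sits at a coordinate on [0.5, K + 0.5] and derives its
admixture proportions from a Gaussian random-walk kernel with spread sigma
around its coordinate.  tau and sigma are fitted so the model attains a target
generalized FST (mean individual inbreeding) and a target ratio of mean
kinship to FST.

Genotypes are drawn hierarchically: ancestral frequencies p_anc from a
sampler (default Uniform(0.01, 0.5)); subpopulation frequencies by
Balding–Nichols drift with inbreeding f_u; individual-specific frequencies
pi = p_sub Q'; genotypes Binomial(2, pi).  Fixed loci are redrawn from
scratch until none remain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from popassoc._util import as_rng, balding_nichols, uniform_p_anc_sampler
from popassoc.data_io import GenotypeMatrix


class AdmixtureFitError(RuntimeError):
    """Target mean-kinship ratio is unattainable at any spread sigma."""


@dataclass
class AdmixtureModel:
    """Fitted admixture model: proportions, subpopulation inbreeding, geography."""

    Q: np.ndarray  # (n, K) admixture proportions, rows sum to 1
    F: np.ndarray  # (K,) subpopulation total inbreeding, u * tau
    tau: float
    sigma: float
    coords: np.ndarray  # (n,) individual coordinates
    subpop_coords: np.ndarray  # (K,) subpopulation coordinates 1..K

    @property
    def n(self) -> int:
        return self.Q.shape[0]

    @property
    def K(self) -> int:
        return self.Q.shape[1]

    def coancestry(self) -> np.ndarray:
        return admixture_coancestry(self.Q, self.F)

    def fst(self) -> float:
        """Generalized FST: uniform-weight mean individual inbreeding."""
        return float(np.mean(np.diag(self.coancestry())))


def individual_coords(n: int, K: int) -> np.ndarray:
    """n coordinates evenly spread over [0.5, K + 0.5]."""
    return 0.5 + K * (np.arange(n) + 0.5) / n


def admixture_proportions_1d(
    n: int, K: int, sigma: float, coords: np.ndarray | None = None
) -> np.ndarray:
    """Admixture proportions from a Gaussian kernel on the 1D geography.

    q_ju is proportional to exp(-(coord_j - u)^2 / (2 sigma^2)), normalized
    per individual.  sigma = 0 assigns each individual fully to its nearest
    subpopulation; sigma < 0 is a domain error.
    """
    if n < 1 or K < 2:
        raise ValueError("need n >= 1 individuals and K >= 2 subpopulations")
    if sigma < 0:
        raise ValueError(f"sigma={sigma} must be >= 0")
    if coords is None:
        coords = individual_coords(n, K)
    subpop_coords = np.arange(1, K + 1, dtype=float)
    dist = coords[:, None] - subpop_coords[None, :]
    if sigma == 0.0:
        Q = np.zeros((n, K))
        Q[np.arange(n), np.argmin(np.abs(dist), axis=1)] = 1.0
        return Q
    logq = -(dist**2) / (2.0 * sigma**2)
    logq -= logq.max(axis=1, keepdims=True)  # avoid underflow at tiny sigma
    Q = np.exp(logq)
    Q /= Q.sum(axis=1, keepdims=True)
    return Q


def admixture_coancestry(Q: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Coancestry induced by independent intermediate subpopulations.

    theta_jk = sum_u q_ju q_ku f_u; the diagonal holds individual inbreeding.
    """
    Q = np.asarray(Q, dtype=float)
    F = np.asarray(F, dtype=float)
    if Q.ndim != 2 or F.shape != (Q.shape[1],):
        raise ValueError("Q must be n x K and F length K")
    if not np.allclose(Q.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("rows of Q must sum to 1")
    return (Q * F) @ Q.T


def _kinship_ratio(sigma: float, n: int, K: int) -> float:
    """Mean off-diagonal coancestry over FST; tau-free for linear F."""
    Q = admixture_proportions_1d(n, K, sigma)
    theta = admixture_coancestry(Q, np.arange(1, K + 1, dtype=float))
    diag = np.diag(theta)
    fst = diag.mean()
    off = (theta.sum() - diag.sum()) / (n * (n - 1))
    return off / fst


def fit_admixture_model(
    n: int,
    K: int,
    fst_target: float = 0.1,
    kinship_ratio: float = 0.5,
    sigma_bounds: tuple[float, float] = (1e-3, 1e3),
) -> AdmixtureModel:
    """Fit sigma and tau so FST and mean-kinship ratio hit their targets.

    The kinship ratio (mean off-diagonal coancestry / FST) is independent of
    tau because both numerator and denominator are linear in tau; it increases
    monotonically with sigma, so sigma is found by root bracketing, after
    which tau rescales FST in closed form.  The fit is deterministic.
    """
    if not 0.0 < fst_target < 1.0:
        raise ValueError("fst_target must lie in (0, 1)")
    if not 0.0 < kinship_ratio < 1.0:
        raise ValueError("kinship_ratio must lie in (0, 1)")
    lo, hi = sigma_bounds
    r_lo, r_hi = (_kinship_ratio(s, n, K) for s in (lo, hi))
    if not r_lo <= kinship_ratio <= r_hi:
        raise AdmixtureFitError(
            f"kinship ratio {kinship_ratio} unattainable for K={K}: "
            f"attainable range [{r_lo:.6f}, {r_hi:.6f}] over sigma in {sigma_bounds}"
        )
    log_sigma = brentq(
        lambda t: _kinship_ratio(np.exp(t), n, K) - kinship_ratio,
        np.log(lo),
        np.log(hi),
        xtol=1e-12,
    )
    sigma = float(np.exp(log_sigma))
    Q = admixture_proportions_1d(n, K, sigma)
    u = np.arange(1, K + 1, dtype=float)
    # FST at tau=1 is mean_j sum_u q_ju^2 u; scale linearly
    fst_unit = float(np.mean((Q**2) @ u))
    tau = fst_target / fst_unit
    F = u * tau
    if F[-1] > 1.0:
        raise AdmixtureFitError(
            f"fitted tau={tau:.6g} gives subpopulation inbreeding > 1"
        )
    return AdmixtureModel(
        Q=Q,
        F=F,
        tau=tau,
        sigma=sigma,
        coords=individual_coords(n, K),
        subpop_coords=u,
    )


@dataclass
class AlleleFrequencySet:
    """Ancestral, subpopulation, and individual-specific allele frequencies."""

    p_anc: np.ndarray  # (m,)
    p_sub: np.ndarray  # (m, K)
    pi: np.ndarray  # (m, n)


def draw_admixture_genotypes(
    model: AdmixtureModel,
    m: int,
    p_anc_sampler=None,
    rng: np.random.Generator | int | None = None,
    max_redraw_rounds: int = 1000,
) -> tuple[GenotypeMatrix, AlleleFrequencySet]:
    """Draw m polymorphic loci for the model's n individuals.

    Loci fixed across all individuals are redrawn wholesale (new ancestral
    frequency onward) until none remain, so the output never contains
    monomorphic loci.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = as_rng(rng)
    if p_anc_sampler is None:
        p_anc_sampler = uniform_p_anc_sampler()

    def draw_block(size: int):
        p_anc = np.asarray(p_anc_sampler(size, rng), dtype=float)
        if not np.all(np.isfinite(p_anc)) or np.any((p_anc <= 0) | (p_anc >= 1)):
            raise ValueError("p_anc_sampler must return frequencies in (0, 1)")
        p_sub = np.empty((size, model.K))
        for u in range(model.K):
            p_sub[:, u] = balding_nichols(p_anc, model.F[u], rng)
        pi = p_sub @ model.Q.T
        if not np.all(np.isfinite(pi)):
            raise RuntimeError("non-finite individual-specific frequencies")
        x = rng.binomial(2, pi).astype(np.int8)
        return p_anc, p_sub, pi, x

    p_anc, p_sub, pi, x = draw_block(m)
    for _ in range(max_redraw_rounds):
        fixed = np.all(x == x[:, :1], axis=1) & (
            (x[:, 0] == 0) | (x[:, 0] == 2)
        )
        if not fixed.any():
            break
        idx = np.flatnonzero(fixed)
        p_anc[idx], p_sub[idx], pi[idx], x[idx] = draw_block(idx.size)
    else:
        raise RuntimeError(
            f"fixed loci remained after {max_redraw_rounds} redraw rounds"
        )

    G = GenotypeMatrix(
        dosages=x,
        locus_ids=[f"snp{i}" for i in range(m)],
        individual_ids=[f"ind{j}" for j in range(model.n)],
    )
    return G, AlleleFrequencySet(p_anc=p_anc, p_sub=p_sub, pi=pi)
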