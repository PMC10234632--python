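"""Native association tests: PCA-covariate OLS and LMM score tests.

PCA association regresses the trait on each locus with an intercept, the top
r principal components (eigenvectors of the standard kinship estimate), and
any extra covariates, testing the locus coefficient with a two-sided t-test.

LMM association fits the null variance components once per trait by REML
under y ~ Normal(X b, 2 sig_s^2 Phi + sig_e^2 I), then evaluates every locus
with a score test (x' P y)^2 / (x' P x) ~ chi^2_1, where P projects out the
fixed effects under the null covariance.  The REML objective is profiled
down to a 1D optimization over the variance ratio via an eigendecomposition
of 2 Phi, so the per-trait cost is one symmetric eigendecomposition plus a
scalar search; no per-locus refitting is done.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from popassoc.data_io import GenotypeMatrix
from popassoc.kinship import standard_kinship


@dataclass
class AssocResult:
    """Per-locus association output for one model fit."""

    locus_ids: list[str]
    beta: np.ndarray
    stat: np.ndarray
    pvalues: np.ndarray
    method: str
    r: int
    df: int | None = None
    variance_components: "VarianceComponents | None" = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": self.locus_ids,
                "beta": self.beta,
                "stat": self.stat,
                "pvalue": self.pvalues,
            }
        )


@dataclass
class VarianceComponents:
    """REML variance component estimates for the LMM null model."""

    sigma_s2: float
    sigma_e2: float
    log_restricted_likelihood: float
    ratio: float = field(default=np.nan)  # sigma_s2 / sigma_e2


def compute_pcs(
    source: GenotypeMatrix | np.ndarray, r: int, maf_min: float = 0.1
) -> np.ndarray:
    """Top-r eigenvectors of the standard kinship estimate, orthonormal.

    Given genotypes, loci with MAF < ``maf_min`` are removed before the
    kinship estimate (the convention of standard PCA association tooling);
    a precomputed kinship matrix is used as-is.  Because standardized
    genotypes are centered, the returned PCs are orthogonal to the
    all-ones vector.
    """
    if isinstance(source, GenotypeMatrix):
        keep = source.maf() >= maf_min
        G = GenotypeMatrix(
            dosages=source.dosages[keep],
            locus_ids=[l for l, k in zip(source.locus_ids, keep) if k],
            individual_ids=list(source.individual_ids),
            missing_mask=None
            if source.missing_mask is None
            else source.missing_mask[keep],
        )
        phi = standard_kinship(G)
    else:
        phi = np.asarray(source, dtype=float)
    n = phi.shape[0]
    if not 0 <= r < n:
        raise ValueError(f"need 0 <= r < n, got r={r}, n={n}")
    if r == 0:
        return np.empty((n, 0))
    vals, vecs = np.linalg.eigh(phi)
    top = vecs[:, ::-1][:, :r]
    # deterministic sign: largest-magnitude entry positive
    flips = np.sign(top[np.argmax(np.abs(top), axis=0), np.arange(r)])
    flips[flips == 0] = 1.0
    return top * flips


def _design(
    n: int, U: np.ndarray | None, Z: np.ndarray | None
) -> np.ndarray:
    cols = [np.ones((n, 1))]
    if U is not None and U.size:
        cols.append(np.asarray(U, dtype=float))
    if Z is not None:
        Z = np.asarray(Z, dtype=float)
        if Z.shape[0] != n:  # accept (k, n) designs transposed
            Z = Z.T
        cols.append(Z)
    W = np.hstack(cols)
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise ValueError("fixed-effect design is rank deficient (collinear "
                         "intercept/PC/covariate columns)")
    return W


def pca_assoc(
    G: GenotypeMatrix,
    y: np.ndarray,
    U: np.ndarray | None = None,
    Z: np.ndarray | None = None,
) -> AssocResult:
    """Per-locus OLS with covariates, two-sided t-test on the locus term.

    Computed by the Frisch–Waugh–Lovell projection: y and every locus are
    residualized on [1, U, Z] once, then each locus is a simple regression
    with n - (#covariates + 2) residual degrees of freedom.  Loci collinear
    with the covariates get NaN results and a warning.
    """
    y = np.asarray(y, dtype=float)
    n = G.n
    if y.shape != (n,):
        raise ValueError("y must be length n")
    W = _design(n, U, Z)
    k = W.shape[1]
    df = n - k - 1
    if df <= 0:
        raise ValueError("not enough residual degrees of freedom")
    Q, _ = np.linalg.qr(W)
    X = G.dosages.astype(float).T  # (n, m)
    Xr = X - Q @ (Q.T @ X)
    yr = y - Q @ (Q.T @ y)
    sxx = np.einsum("ij,ij->j", Xr, Xr)
    sxy = Xr.T @ yr
    syy = float(yr @ yr)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = syy - beta * sxy
        sigma2 = rss / df
        tstat = beta / np.sqrt(sigma2 / sxx)
    degenerate = sxx <= 1e-12 * n
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} loci collinear with covariates; "
            "skipped (NaN)",
            RuntimeWarning,
        )
        beta[degenerate] = np.nan
        tstat[degenerate] = np.nan
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    return AssocResult(
        locus_ids=list(G.locus_ids),
        beta=beta,
        stat=tstat,
        pvalues=pvals,
        method="pca",
        r=0 if U is None else U.shape[1],
        df=df,
    )


def _reml_profile(
    lam: np.ndarray, yt: np.ndarray, Xt: np.ndarray
) -> tuple:
    """Return f(log-ratio) -> (negative restricted LL, sigma_e2 profile)."""
    n, k = Xt.shape

    def negloglik(log_gamma: float) -> tuple[float, float]:
        gamma = np.exp(log_gamma)
        d = 1.0 + gamma * lam
        w = 1.0 / d
        Xw = Xt * w[:, None]
        B = Xt.T @ Xw
        coef = np.linalg.solve(B, Xw.T @ yt)
        resid = yt - Xt @ coef
        rss = float(resid @ (w * resid))
        sigma_e2 = rss / (n - k)
        _, logdet_b = np.linalg.slogdet(B)
        nll = 0.5 * (
            (n - k) * np.log(sigma_e2)
            + np.sum(np.log(d))
            + logdet_b
            + (n - k)
        )
        return nll, sigma_e2

    return negloglik


def lmm_null_reml(
    y: np.ndarray,
    kinship: np.ndarray,
    U: np.ndarray | None = None,
    Z: np.ndarray | None = None,
    log_ratio_bounds: tuple[float, float] = (-30.0, 30.0),
) -> VarianceComponents:
    """REML variance components for y ~ Normal(X b, 2 sig_s^2 Phi + sig_e^2 I).

    The restricted likelihood is profiled over the variance ratio
    gamma = sig_s^2 / sig_e^2 after rotating by the eigenvectors of 2 Phi;
    gamma is optimized by bounded Brent search on the log scale, with the
    gamma = 0 boundary permitted.  Tiny negative kinship eigenvalues (from
    estimated matrices) are clipped at zero.
    """
    y = np.asarray(y, dtype=float)
    phi = np.asarray(kinship, dtype=float)
    n = y.size
    if phi.shape != (n, n):
        raise ValueError("kinship must be n x n")
    if not np.allclose(phi, phi.T, atol=1e-8):
        raise ValueError("kinship must be symmetric")
    W = _design(n, U, Z)
    if n <= W.shape[1]:
        raise ValueError("more fixed effects than individuals")
    lam, V = np.linalg.eigh(2.0 * phi)
    lam = np.clip(lam, 0.0, None)
    yt = V.T @ y
    Xt = V.T @ W
    negloglik = _reml_profile(lam, yt, Xt)

    res = minimize_scalar(
        lambda t: negloglik(t)[0],
        bounds=log_ratio_bounds,
        method="bounded",
        options={"xatol": 1e-8},
    )
    cands = [(res.fun, float(res.x))]
    # gamma -> 0 boundary (no genetic variance)
    nll0, _ = negloglik(log_ratio_bounds[0] - 10.0)
    cands.append((nll0, log_ratio_bounds[0] - 10.0))
    nll_best, t_best = min(cands)
    if not np.isfinite(nll_best):
        raise RuntimeError("non-finite restricted likelihood")
    gamma = np.exp(t_best)
    _, sigma_e2 = negloglik(t_best)
    if t_best <= log_ratio_bounds[0] - 10.0 + 1e-12:
        gamma = 0.0
    return VarianceComponents(
        sigma_s2=gamma * sigma_e2,
        sigma_e2=sigma_e2,
        log_restricted_likelihood=-nll_best,
        ratio=gamma,
    )


class LmmWorkspace:
    """Amortizes the kinship eigendecomposition and genotype rotation.

    Running the LMM at several PC counts r on the same trait and genotypes
    only changes the fixed-effect design, so the expensive pieces — the
    eigendecomposition of 2 Phi and the rotation of the genotype matrix —
    are computed once and reused across calls to :meth:`assoc`.
    """

    def __init__(self, G: GenotypeMatrix, y: np.ndarray, kinship: np.ndarray):
        y = np.asarray(y, dtype=float)
        phi = np.asarray(kinship, dtype=float)
        n = G.n
        if y.shape != (n,):
            raise ValueError("y must be length n")
        if phi.shape != (n, n):
            raise ValueError("kinship must be n x n")
        if not np.allclose(phi, phi.T, atol=1e-8):
            raise ValueError("kinship must be symmetric")
        lam, V = np.linalg.eigh(2.0 * phi)
        self.lam = np.clip(lam, 0.0, None)
        self.V = V
        self.yt = V.T @ y
        self.Gt = V.T @ G.dosages.astype(float).T  # (n, m)
        self.G = G
        self.n = n

    def null_reml(
        self, U: np.ndarray | None = None, Z: np.ndarray | None = None
    ) -> VarianceComponents:
        W = _design(self.n, U, Z)
        if self.n <= W.shape[1]:
            raise ValueError("more fixed effects than individuals")
        negloglik = _reml_profile(self.lam, self.yt, self.V.T @ W)
        res = minimize_scalar(
            lambda t: negloglik(t)[0],
            bounds=(-30.0, 30.0),
            method="bounded",
            options={"xatol": 1e-8},
        )
        cands = [(res.fun, float(res.x))]
        nll0, _ = negloglik(-40.0)  # gamma -> 0 boundary
        cands.append((nll0, -40.0))
        nll_best, t_best = min(cands)
        if not np.isfinite(nll_best):
            raise RuntimeError("non-finite restricted likelihood")
        gamma = np.exp(t_best)
        _, sigma_e2 = negloglik(t_best)
        if t_best <= -40.0 + 1e-12:
            gamma = 0.0
        return VarianceComponents(
            sigma_s2=gamma * sigma_e2,
            sigma_e2=sigma_e2,
            log_restricted_likelihood=-nll_best,
            ratio=gamma,
        )

    def assoc(
        self,
        U: np.ndarray | None = None,
        Z: np.ndarray | None = None,
        vc: VarianceComponents | None = None,
    ) -> AssocResult:
        W = _design(self.n, U, Z)
        if vc is None:
            vc = self.null_reml(U=U, Z=Z)
        d = vc.sigma_s2 * self.lam + vc.sigma_e2  # rotated-basis variances
        if np.any(d <= 0):
            raise RuntimeError("null covariance is singular")
        Xt = self.V.T @ W
        winv = 1.0 / d
        wy = winv * self.yt
        B = Xt.T @ (Xt * winv[:, None])
        Binv = np.linalg.inv(B)
        Xw_y = Xt.T @ wy  # (k,)
        a = self.Gt.T @ wy  # x' Vinv y per locus
        C = self.Gt.T @ (Xt * winv[:, None])  # (m, k): x' Vinv X
        q = np.einsum("ij,ij->j", self.Gt * winv[:, None], self.Gt)
        num = a - C @ (Binv @ Xw_y)
        den = q - np.einsum("ij,ij->i", C @ Binv, C)
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = num**2 / den
            beta = num / den
        pos = den[den > 0]
        degenerate = den <= (1e-12 * np.median(pos) if pos.size else np.inf)
        if degenerate.any():
            warnings.warn(
                f"{int(degenerate.sum())} loci collinear with covariates; "
                "skipped (NaN)",
                RuntimeWarning,
            )
            stat[degenerate] = np.nan
            beta[degenerate] = np.nan
        pvals = stats.chi2.sf(stat, 1)
        return AssocResult(
            locus_ids=list(self.G.locus_ids),
            beta=beta,
            stat=stat,
            pvalues=pvals,
            method="lmm",
            r=0 if U is None else U.shape[1],
            variance_components=vc,
        )


def lmm_assoc(
    G: GenotypeMatrix,
    y: np.ndarray,
    kinship: np.ndarray,
    U: np.ndarray | None = None,
    Z: np.ndarray | None = None,
    vc: VarianceComponents | None = None,
) -> AssocResult:
    """LMM score test per locus under the null variance components.

    The null model (fixed effects [1, U, Z]) is fitted once by REML unless
    precomputed components are supplied; each locus is then scored with
    (x' P y)^2 / (x' P x) against chi^2 with 1 degree of freedom, where
    P = Vinv - Vinv X (X' Vinv X)^-1 X' Vinv.
    """
    return LmmWorkspace(G, y, kinship).assoc(U=U, Z=Z, vc=vc)
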