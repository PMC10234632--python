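"""Kinship and coancestry estimation from genotypes.

Three estimators are provided:

* ``standard_kinship`` — the textbook method-of-moments estimator on
  standardized genotypes, Phi = X_S' X_S / m with per-locus standardization
  by estimated allele frequencies.  Its rows sum to zero by construction,
  which encodes its well-known bias: relatedness is measured against the
  sample mean rather than the ancestral population.
* ``corrected_kinship`` — a ratio-of-means estimator that removes that bias
  by normalizing against the most-unrelated pairs in the sample, so the
  minimum coancestry maps to zero and the ancestral reference is recovered.
* ``king_robust`` — the KING-robust *local* (pedigree) kinship estimator
  built from within-pair heterozygote and opposite-homozygote counts; it is
  robust to population structure and may be negative between members of
  different subpopulations.

``filter_relatives`` applies the usual greedy relative-pruning with the
4th-degree cutoff 2^(-11/2).
"""

from __future__ import annotations

import warnings

import numpy as np

from popassoc.data_io import GenotypeMatrix

#: KING-robust kinship cutoff excluding up to 4th-degree relatives.
KING_CUTOFF_4TH_DEGREE = 2.0 ** (-11.0 / 2.0)


def _dosage_float(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray | None]:
    x = G.dosages.astype(float)
    mask = G.missing_mask
    if mask is not None and not mask.any():
        mask = None
    return x, mask


def standard_kinship(G: GenotypeMatrix) -> np.ndarray:
    """Method-of-moments kinship from standardized genotypes.

    Loci with any missing genotype are dropped (simulated data has none).
    Monomorphic loci are an error: their standardization divides by zero.
    """
    x, mask = _dosage_float(G)
    if mask is not None:
        keep = ~mask.any(axis=1)
        x = x[keep]
    m = x.shape[0]
    if m == 0:
        raise ValueError("no complete loci available")
    p_hat = x.mean(axis=1) / 2.0
    if np.any((p_hat <= 0.0) | (p_hat >= 1.0)):
        raise ValueError(
            "monomorphic loci present; filter by MAF before estimating kinship"
        )
    xs = (x - 2.0 * p_hat[:, None]) / np.sqrt(
        4.0 * p_hat * (1.0 - p_hat)
    )[:, None]
    phi = xs.T @ xs / m
    return (phi + phi.T) / 2.0


def corrected_kinship(
    G: GenotypeMatrix,
    labels: np.ndarray | list | None = None,
    min_quantile: float = 0.01,
    unrelated_threshold: float = 0.01,
) -> np.ndarray:
    """Bias-corrected kinship via ratio of means.

    A_jk = mean_i (x_ij - 1)(x_ik - 1) - 1 estimates 4 v_bar (phi_jk - 1),
    with v_bar the mean ancestral allele variance, so Phi = 1 - A / A_min is
    unbiased once A_min estimates the same quantity for truly unrelated
    pairs.  A_min is taken as the mean A over the most-unrelated pair set:
    the minimum between-group block mean when subpopulation ``labels`` are
    given, otherwise the mean over the bottom ``min_quantile`` fraction of
    off-diagonal A values (at least one pair), refined by re-averaging over
    all pairs whose estimated kinship falls below ``unrelated_threshold``.
    """
    x, mask = _dosage_float(G)
    if mask is not None:
        keep = ~mask.any(axis=1)
        x = x[keep]
    m, n = x.shape
    if n < 3:
        raise ValueError("need at least 3 individuals")
    if m == 0:
        raise ValueError("no complete loci available")
    p_hat = x.mean(axis=1) / 2.0
    if np.any((p_hat <= 0.0) | (p_hat >= 1.0)):
        raise ValueError(
            "monomorphic loci present; filter by MAF before estimating kinship"
        )
    xc = x - 1.0
    A = xc.T @ xc / m - 1.0
    if labels is not None:
        labels = np.asarray(labels)
        if labels.shape[0] != n:
            raise ValueError("labels length mismatch")
        uniq = np.unique(labels)
        if len(uniq) < 2:
            raise ValueError("need >= 2 distinct labels to anchor the minimum")
        block_means = []
        for a in range(len(uniq)):
            for b in range(a + 1, len(uniq)):
                sel = A[np.ix_(labels == uniq[a], labels == uniq[b])]
                block_means.append(sel.mean())
        a_min = min(block_means)
    else:
        iu = np.triu_indices(n, k=1)
        offdiag = A[iu]
        k = max(1, int(np.floor(min_quantile * offdiag.size)))
        a_min = np.sort(offdiag)[:k].mean()
        # refine the unrelated set: re-anchor on all pairs whose current
        # estimate is below the threshold, which averages away the noise
        # selection of the initial bottom-quantile anchor
        for _ in range(3):
            phi_off = 1.0 - offdiag / a_min
            sel = phi_off < unrelated_threshold
            if not sel.any():
                break
            a_min = offdiag[sel].mean()
    if a_min >= 0:
        raise ValueError("most-unrelated pair statistic is non-negative; "
                         "cannot anchor the kinship scale")
    phi = 1.0 - A / a_min
    return (phi + phi.T) / 2.0


def coancestry_from_kinship(phi: np.ndarray) -> np.ndarray:
    """Coancestry: off-diagonal kinship unchanged, diagonal f_j = 2 phi_jj - 1."""
    phi = np.asarray(phi, dtype=float)
    if phi.ndim != 2 or phi.shape[0] != phi.shape[1]:
        raise ValueError("kinship must be square")
    theta = phi.copy()
    np.fill_diagonal(theta, 2.0 * np.diag(phi) - 1.0)
    return theta


def king_robust(G: GenotypeMatrix) -> np.ndarray:
    """KING-robust local kinship.

    phi_jk = (N_het,het - 2 N_opposite-hom) / (N_het(j) + N_het(k)) over loci
    complete for the pair.  Pairs with no heterozygous loci are undefined and
    returned as NaN with a warning.  The diagonal is set to 1/2 by convention.
    """
    x, mask = _dosage_float(G)
    valid = np.ones_like(x) if mask is None else (~mask).astype(float)
    het = ((x == 1) & (valid > 0)).astype(float)
    hom0 = ((x == 0) & (valid > 0)).astype(float)
    hom2 = ((x == 2) & (valid > 0)).astype(float)
    n_hh = het.T @ het
    n_opp = hom0.T @ hom2
    n_opp = n_opp + n_opp.T  # both orders: total opposite-homozygote loci
    # heterozygote count of j over loci complete for the pair (j, k)
    n_het_pair = het.T @ valid
    denom = n_het_pair + n_het_pair.T
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (n_hh - 2.0 * n_opp) / denom
    phi[denom == 0] = np.nan
    if np.any(denom[np.triu_indices_from(denom, k=1)] == 0):
        warnings.warn(
            "pairs with zero heterozygous loci: local kinship undefined (NaN)",
            RuntimeWarning,
        )
    phi = (phi + phi.T) / 2.0
    np.fill_diagonal(phi, 0.5)
    return phi


def filter_relatives(
    phi_local: np.ndarray, cutoff: float = KING_CUTOFF_4TH_DEGREE
) -> np.ndarray:
    """Greedy relative pruning; returns indices of kept individuals.

    While any off-diagonal pair is at or above the cutoff, the individual
    participating in the most such pairs is removed (ties: lowest index).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    phi = np.array(phi_local, dtype=float)
    n = phi.shape[0]
    adj = np.nan_to_num(phi, nan=-np.inf) >= cutoff
    np.fill_diagonal(adj, False)
    keep = np.ones(n, dtype=bool)
    while True:
        deg = (adj & keep[None, :] & keep[:, None]).sum(axis=1)
        deg[~keep] = 0
        if deg.max(initial=0) == 0:
            break
        keep[int(np.argmax(deg))] = False  # argmax ties -> lowest index
    return np.flatnonzero(keep)
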