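"""Replicate experiment orchestration and model comparison.

``run_replicates`` repeats, for a configured scenario: draw genotypes
(admixture, admixed family, or subpopulation tree), estimate kinship and
PCs, simulate a heritability-calibrated trait, run both association models
(PCA and LMM) over a grid of PC counts r, and score each run with SRMSDp
(on the null loci), AUCPR, and the inflation factor.  ``compare_models``
summarizes the resulting table the way association-method benchmarks do:
best r per method by mean metric, calibration flags (mean |SRMSDp| < 0.01),
and paired one-tailed Wilcoxon signed-rank tests with a Bonferroni
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from popassoc._util import as_rng
from popassoc.admixture_sim import draw_admixture_genotypes, fit_admixture_model
from popassoc.assoc import compute_pcs, pca_assoc
from popassoc.data_io import GenotypeMatrix
from popassoc.evalmetrics import auc_pr, inflation_lambda, srmsd_p
from popassoc.family_sim import draw_pedigree, drop_genotypes
from popassoc.kinship import standard_kinship
from popassoc.tree_model import SubpopTree, additive_edges, draw_tree_genotypes
from popassoc.trait_sim import simulate_trait_replicate

SCENARIOS = ("admixture-large", "admixture-small", "admixture-family", "tree")


@dataclass
class ExperimentConfig:
    """Scenario, scale, trait model, r grid, and replication settings."""

    scenario: str = "admixture-large"
    n: int = 500
    m: int = 20_000
    K: int = 10
    fst: float = 0.1
    kinship_ratio: float = 0.5
    generations: int = 20
    trait_model: str = "fes"
    h2: float = 0.8
    env_vars: list[float] = field(default_factory=list)
    env_group_counts: list[int] = field(default_factory=list)
    r_grid: list[int] = field(default_factory=lambda: [0, 1, 2, 3, 4, 5])
    replicates: int = 10
    seed: int = 1
    maf_min_causal: float = 0.01
    maf_min_pcs: float = 0.1
    tree_newick: str | None = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if any(r >= self.n for r in self.r_grid):
            raise ValueError("r values must be below n")
        if 1.0 - self.h2 - sum(self.env_vars) < 0:
            raise ValueError("infeasible variance partition")
        if len(self.env_vars) != len(self.env_group_counts):
            raise ValueError("env_vars and env_group_counts must align")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _default_tree(K: int, fst: float) -> SubpopTree:
    """Caterpillar tree with leaf total inbreeding spread around ``fst``."""
    n_nodes = 2 * K - 1
    parent = np.full(n_nodes, -1, dtype=int)
    names = [f"node{i}" for i in range(n_nodes)]
    # chain of internal nodes 0..K-2; leaf w hangs off internal node
    for i in range(1, K - 1):
        parent[i] = i - 1
    leaf_ids = list(range(K - 1, n_nodes))
    for j, leaf in enumerate(leaf_ids):
        parent[leaf] = min(j, K - 2)
        names[leaf] = f"S{j + 1}"
    f_edge = np.zeros(n_nodes)
    f_edge[1 : K - 1] = fst / K
    # leaves get increasing extra drift so node depths are distinct
    f_edge[leaf_ids] = fst * (0.5 + np.arange(K) / K)
    tree = SubpopTree(parent=parent, names=names, f_edge=f_edge)
    return additive_edges(tree)


def _draw_scenario(cfg: ExperimentConfig, rng) -> tuple[GenotypeMatrix, np.ndarray | None]:
    """Scenario-appropriate genotype draw; returns (G, p_anc or None)."""
    if cfg.scenario in ("admixture-large", "admixture-small"):
        model = fit_admixture_model(cfg.n, cfg.K, cfg.fst, cfg.kinship_ratio)
        G, freqs = draw_admixture_genotypes(model, cfg.m, rng=rng)
        return G, freqs.p_anc
    if cfg.scenario == "admixture-family":
        model = fit_admixture_model(cfg.n, cfg.K, cfg.fst, cfg.kinship_ratio)
        founder_G, freqs = draw_admixture_genotypes(model, cfg.m, rng=rng)
        ped = draw_pedigree(model.coords, cfg.generations, cfg.n, rng=rng)
        G = drop_genotypes(ped, founder_G, rng=rng)
        # drift through the pedigree fixes a few loci; drop them, and keep
        # the matching ancestral frequencies aligned
        keep = G.maf() > 0
        from popassoc.data_io import filter_loci

        return filter_loci(G), freqs.p_anc[keep]
    # tree scenario
    if cfg.tree_newick is not None:
        from popassoc.tree_model import from_newick

        tree = from_newick(cfg.tree_newick)
    else:
        tree = _default_tree(cfg.K, cfg.fst)
    per_pop = max(1, cfg.n // len(tree.leaves()))
    G, _ = draw_tree_genotypes(
        tree, per_pop, cfg.m, maf_min=cfg.maf_min_causal, rng=rng
    )
    return G, None


def run_replicates(cfg: ExperimentConfig) -> pd.DataFrame:
    """Run all replicates; one row per (replicate, method, r).

    Failed fits are recorded with NaN metrics rather than aborting the run.
    Columns: replicate, method, r, srmsd_p, auc_pr, lambda_gc, error.
    """
    rows = []
    for rep in range(cfg.replicates):
        rng = as_rng(cfg.seed + rep)
        G, p_anc = _draw_scenario(cfg, rng)
        mean_kin = None
        if p_anc is None:
            from popassoc.kinship import corrected_kinship

            mean_kin = float(corrected_kinship(G).mean())
        tm, trait = simulate_trait_replicate(
            G,
            h2=cfg.h2,
            p_anc=p_anc,
            model=cfg.trait_model,
            env_group_counts=cfg.env_group_counts,
            env_vars=cfg.env_vars,
            mean_kinship=mean_kin,
            maf_min=cfg.maf_min_causal,
            rng=rng,
        )
        null_mask = np.ones(G.m, dtype=bool)
        null_mask[tm.causal] = False
        causal_mask = ~null_mask
        phi = standard_kinship(G)
        from popassoc.assoc import LmmWorkspace

        ws = LmmWorkspace(G, trait.y, phi)
        pcs_full = compute_pcs(G, max(cfg.r_grid), maf_min=cfg.maf_min_pcs) \
            if max(cfg.r_grid) > 0 else np.empty((G.n, 0))

        for r in cfg.r_grid:
            U = pcs_full[:, :r] if r > 0 else None
            for method, runner in (
                ("pca", lambda: pca_assoc(G, trait.y, U=U)),
                ("lmm", lambda: ws.assoc(U=U)),
            ):
                row = {
                    "replicate": rep, "method": method, "r": r,
                    "srmsd_p": np.nan, "auc_pr": np.nan,
                    "lambda_gc": np.nan, "error": "",
                }
                try:
                    res = runner()
                    pv = res.pvalues
                    ok = np.isfinite(pv)
                    row["srmsd_p"] = srmsd_p(pv[null_mask & ok])
                    with np.errstate(divide="ignore"):
                        scores = -np.log10(np.clip(pv, 1e-300, 1.0))
                    row["auc_pr"] = auc_pr(scores, causal_mask)
                    row["lambda_gc"] = inflation_lambda(pv[null_mask & ok])
                except Exception as exc:  # record, keep going
                    row["error"] = f"{type(exc).__name__}: {exc}"
                    warnings.warn(
                        f"replicate {rep} {method} r={r} failed: {exc}",
                        RuntimeWarning,
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def _wilcoxon_paired(
    a: np.ndarray, b: np.ndarray, alternative: str
) -> float:
    """One-tailed paired signed-rank p-value (exact for <= 25 pairs)."""
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size == 0:
        return np.nan
    diffs = a - b
    if np.all(diffs == 0):
        return 1.0
    method = "exact" if (a.size <= 25 and not np.any(diffs == 0)) else "approx"
    return float(
        stats.wilcoxon(a, b, alternative=alternative, method=method).pvalue
    )


def compare_models(
    records: pd.DataFrame, alpha: float = 0.01, n_tests: int = 1
) -> pd.DataFrame:
    """Benchmark summary comparing PCA (best r) against LMM (r = 0).

    For each metric: best r per method by mean (min mean |SRMSDp| or max
    mean AUCPR), calibration flags, and a paired one-tailed Wilcoxon test of
    PCA at its best r against LMM at r = 0; ``winner`` is "Tie" unless
    p < alpha / n_tests.
    """
    req = {"replicate", "method", "r", "srmsd_p", "auc_pr"}
    if not req <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(req)}")
    out = []
    for metric, better in (("srmsd_p", "less"), ("auc_pr", "greater")):
        col = records[metric].abs() if metric == "srmsd_p" else records[metric]
        df = records.assign(val=col)
        means = df.groupby(["method", "r"])["val"].mean()
        best_r = {}
        for method in ("pca", "lmm"):
            sub = means.loc[method]
            best_r[method] = int(
                sub.idxmin() if metric == "srmsd_p" else sub.idxmax()
            )

        def per_rep(method: str, r: int) -> np.ndarray:
            sel = df[(df["method"] == method) & (df["r"] == r)]
            sel = sel.sort_values("replicate")
            if sel["replicate"].duplicated().any():
                raise ValueError("records are not uniquely paired")
            return sel["val"].to_numpy()

        pca_vals = per_rep("pca", best_r["pca"])
        lmm_vals = per_rep("lmm", 0)
        if len(pca_vals) != len(lmm_vals):
            raise ValueError("unpaired records between models")
        # one-tailed: is LMM better than PCA?
        p_lmm_vs_pca = _wilcoxon_paired(lmm_vals, pca_vals, better)
        p_pca_vs_lmm = _wilcoxon_paired(pca_vals, lmm_vals, better)
        threshold = alpha / n_tests
        if p_lmm_vs_pca < threshold:
            winner = "LMM"
        elif p_pca_vs_lmm < threshold:
            winner = "PCA"
        else:
            winner = "Tie"
        row = {
            "metric": metric,
            "trait_model": records.attrs.get("trait_model", ""),
            "best_r_pca": best_r["pca"],
            "best_r_lmm": best_r["lmm"],
            "pvalue": p_lmm_vs_pca,
            "winner": winner,
        }
        if metric == "srmsd_p":
            row["calibrated_pca"] = bool(np.nanmean(pca_vals) < 0.01)
            row["calibrated_lmm"] = bool(np.nanmean(lmm_vals) < 0.01)
        out.append(row)
    return pd.DataFrame(out)


def plot_metric_distributions(records: pd.DataFrame, path: str | Path) -> None:
    """Distributions of SRMSDp and AUCPR over r for both methods."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
    rs = sorted(records["r"].unique())
    for ax, metric in zip(axes, ("srmsd_p", "auc_pr")):
        for method, color in (("pca", "tab:blue"), ("lmm", "tab:red")):
            sub = records[records["method"] == method]
            data = [
                sub[sub["r"] == r][metric].dropna().to_numpy() for r in rs
            ]
            pos = np.arange(len(rs)) + (-0.15 if method == "pca" else 0.15)
            bp = ax.boxplot(
                data, positions=pos, widths=0.25, patch_artist=True,
                manage_ticks=False,
            )
            for patch in bp["boxes"]:
                patch.set_facecolor(color)
        ax.set_ylabel(metric)
        if metric == "srmsd_p":
            ax.axhspan(-0.01, 0.01, color="0.9")
    axes[1].set_xticks(np.arange(len(rs)))
    axes[1].set_xticklabels([str(r) for r in rs])
    axes[1].set_xlabel("number of PCs (r)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
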