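"""Random multi-generation pedigrees with geographically assortative mating.

Generation 1 holds n admixed founders ordered along a 1D geography; they are
locally unrelated and outbred.  Each later generation is built by pairing
random males with the nearest available female whose local (pedigree)
kinship is below a cutoff (default 1/4^3, excluding second cousins and
closer), drawing family sizes as n_min + Poisson(n/n_f - n_min), and
rebalancing family sizes until the generation has exactly n children.
Children take the mean parental coordinate (preserving the geography) and a
random sex.  Genotypes are dropped through the pedigree one allele per
parent per locus, independently across loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from popassoc._util import as_rng
from popassoc.data_io import GenotypeMatrix, SampleAnnotation

DEFAULT_PAIRING_CUTOFF = 0.25**3  # second cousins (kinship 1/64) still mate


class PedigreeError(RuntimeError):
    """Pedigree construction failed (e.g. no valid pairs in a generation)."""


@dataclass
class Pedigree:
    """Flat pedigree record: one row per individual across all generations.

    ``father`` / ``mother`` are global row indices (-1 for founders).
    Each generation has exactly ``n`` individuals.
    """

    id: list[str]
    generation: np.ndarray  # 1-based
    father: np.ndarray
    mother: np.ndarray
    sex: np.ndarray  # "female" / "male"
    coordinate: np.ndarray

    def __post_init__(self) -> None:
        self.generation = np.asarray(self.generation, dtype=int)
        self.father = np.asarray(self.father, dtype=int)
        self.mother = np.asarray(self.mother, dtype=int)
        self.sex = np.asarray(self.sex, dtype=object)
        self.coordinate = np.asarray(self.coordinate, dtype=float)

    @property
    def n_total(self) -> int:
        return len(self.id)

    @property
    def n_generations(self) -> int:
        return int(self.generation.max())

    def generation_indices(self, g: int) -> np.ndarray:
        return np.flatnonzero(self.generation == g)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.id,
                "generation": self.generation,
                "father": [self.id[f] if f >= 0 else "" for f in self.father],
                "mother": [self.id[m] if m >= 0 else "" for m in self.mother],
                "sex": self.sex,
                "coordinate": self.coordinate,
            }
        )


def _pair_generation(
    coords: np.ndarray,
    sex: np.ndarray,
    kin: np.ndarray,
    cutoff: float,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Single pairing pass: random males to nearest eligible females."""
    males = list(np.flatnonzero(sex == "male"))
    females = list(np.flatnonzero(sex == "female"))
    pairs: list[tuple[int, int]] = []
    while males and females:
        mi = males.pop(int(rng.integers(len(males))))
        fem = np.asarray(females)
        ok = kin[mi, fem] < cutoff
        if not ok.any():
            continue  # male stays unpaired
        cand = fem[ok]
        d = np.abs(coords[cand] - coords[mi])
        # nearest coordinate, ties by lowest index
        best = cand[np.lexsort((cand, d))][0]
        pairs.append((mi, int(best)))
        females.remove(int(best))
    return pairs


def _family_sizes(
    n: int, n_f: int, n_min: int, rng: np.random.Generator,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Poisson family sizes delta-rebalanced to sum exactly to n."""
    rate = max(n / n_f - n_min, 0.0)
    sizes = n_min + rng.poisson(rate, size=n_f)
    for _ in range(max_iter):
        delta = n - int(sizes.sum())
        if delta == 0:
            return sizes
        if delta > 0:
            if delta >= n_f:
                sizes += 1
            else:
                sizes[rng.choice(n_f, size=delta, replace=False)] += 1
        else:
            eligible = np.flatnonzero(sizes > n_min)
            if eligible.size == 0:
                raise PedigreeError(
                    "cannot shrink families below the minimum size"
                )
            k = min(-delta, eligible.size)
            sizes[rng.choice(eligible, size=k, replace=False)] -= 1
    raise PedigreeError("family-size rebalancing did not converge")


def draw_pedigree(
    founders: SampleAnnotation | np.ndarray,
    G: int,
    n: int,
    cutoff: float = DEFAULT_PAIRING_CUTOFF,
    n_min: int = 1,
    rng: np.random.Generator | int | None = None,
) -> Pedigree:
    """Draw a G-generation pedigree with n individuals per generation.

    ``founders`` supplies the n founder coordinates (a SampleAnnotation with
    coordinates, or a coordinate array), which must be sorted.
    """
    if G < 1 or n < 2:
        raise ValueError("need G >= 1 and n >= 2")
    if not 0.0 < cutoff <= 0.5:
        raise ValueError("cutoff must lie in (0, 1/2]")
    rng = as_rng(rng)
    if isinstance(founders, SampleAnnotation):
        if founders.coordinate is None:
            raise ValueError("founder annotation lacks coordinates")
        coords0 = np.asarray(founders.coordinate, dtype=float)
        ids0 = list(founders.individual_id)
    else:
        coords0 = np.asarray(founders, dtype=float)
        ids0 = [f"g1-{j}" for j in range(len(coords0))]
    if coords0.size != n:
        raise ValueError("founders must have exactly n individuals")
    if np.any(np.diff(coords0) < 0):
        raise ValueError("founders must be ordered by coordinate")

    ids = list(ids0)
    generation = [np.ones(n, dtype=int)]
    father = [np.full(n, -1, dtype=int)]
    mother = [np.full(n, -1, dtype=int)]
    sexes = [np.where(rng.random(n) < 0.5, "female", "male").astype(object)]
    coords = [coords0.copy()]

    # local kinship within the current generation
    kin = np.eye(n) / 2.0
    offset = 0  # global index of first individual of current generation
    for g in range(2, G + 1):
        pairs = _pair_generation(coords[-1], sexes[-1], kin, cutoff, rng)
        n_f = len(pairs)
        if n_f == 0:
            raise PedigreeError(f"no valid pairs in generation {g - 1}")
        sizes = _family_sizes(n, n_f, n_min, rng)
        fa = np.repeat([p[0] for p in pairs], sizes)
        mo = np.repeat([p[1] for p in pairs], sizes)
        child_coord = (coords[-1][fa] + coords[-1][mo]) / 2.0
        order = np.argsort(child_coord, kind="stable")
        fa, mo, child_coord = fa[order], mo[order], child_coord[order]

        # next-generation local kinship from the recursion
        cross = 0.25 * (
            kin[np.ix_(fa, fa)]
            + kin[np.ix_(fa, mo)]
            + kin[np.ix_(mo, fa)]
            + kin[np.ix_(mo, mo)]
        )
        np.fill_diagonal(cross, 0.5 * (1.0 + kin[fa, mo]))
        kin = cross

        new_offset = offset + n
        ids.extend(f"g{g}-{j}" for j in range(n))
        generation.append(np.full(n, g, dtype=int))
        father.append(offset + fa)
        mother.append(offset + mo)
        sexes.append(
            np.where(rng.random(n) < 0.5, "female", "male").astype(object)
        )
        coords.append(child_coord)
        offset = new_offset

    return Pedigree(
        id=ids,
        generation=np.concatenate(generation),
        father=np.concatenate(father),
        mother=np.concatenate(mother),
        sex=np.concatenate(sexes),
        coordinate=np.concatenate(coords),
    )


def pedigree_kinship(
    ped: Pedigree, founder_coancestry: np.ndarray | None = None
) -> list[np.ndarray]:
    """Within-generation kinship matrices via the standard recursion.

    phi(child, x) = (phi(father, x) + phi(mother, x)) / 2 for x not a
    descendant, and phi(child, child) = (1 + phi(father, mother)) / 2.
    With ``founder_coancestry`` None, founders are unrelated and outbred
    (local kinship); otherwise founder kinship is seeded from the coancestry
    matrix (diagonal (1 + f_j) / 2), yielding total kinship combining
    ancestry and pedigree.  Returns one n x n matrix per generation.
    """
    g1 = ped.generation_indices(1)
    n = g1.size
    if founder_coancestry is None:
        kin = np.eye(n) / 2.0
    else:
        theta = np.asarray(founder_coancestry, dtype=float)
        if theta.shape != (n, n):
            raise ValueError("founder_coancestry must be n x n")
        kin = theta.copy()
        np.fill_diagonal(kin, (1.0 + np.diag(theta)) / 2.0)
    out = [kin]
    for g in range(2, ped.n_generations + 1):
        idx = ped.generation_indices(g)
        prev = ped.generation_indices(g - 1)
        pos = {int(i): k for k, i in enumerate(prev)}
        fa = np.array([pos[int(f)] for f in ped.father[idx]])
        mo = np.array([pos[int(m)] for m in ped.mother[idx]])
        kin_prev = out[-1]
        kin = 0.25 * (
            kin_prev[np.ix_(fa, fa)]
            + kin_prev[np.ix_(fa, mo)]
            + kin_prev[np.ix_(mo, fa)]
            + kin_prev[np.ix_(mo, mo)]
        )
        np.fill_diagonal(kin, 0.5 * (1.0 + kin_prev[fa, mo]))
        out.append(kin)
    return out


def drop_genotypes(
    ped: Pedigree,
    founder_G: GenotypeMatrix,
    rng: np.random.Generator | int | None = None,
) -> GenotypeMatrix:
    """Mendelian genotype dropping; returns the last generation's genotypes.

    Each child receives one allele from each parent per locus: a
    Bernoulli(dosage / 2) draw per parent, independent across loci.
    """
    rng = as_rng(rng)
    g1 = ped.generation_indices(1)
    if founder_G.n != g1.size:
        raise ValueError("founder genotypes do not match founder count")
    if founder_G.missing_mask is not None and founder_G.missing_mask.any():
        raise ValueError("founder genotypes must be complete")
    x = founder_G.dosages
    for g in range(2, ped.n_generations + 1):
        idx = ped.generation_indices(g)
        prev = ped.generation_indices(g - 1)
        pos = {int(i): k for k, i in enumerate(prev)}
        fa = np.array([pos[int(f)] for f in ped.father[idx]])
        mo = np.array([pos[int(m)] for m in ped.mother[idx]])
        x = (
            rng.binomial(1, x[:, fa] / 2.0) + rng.binomial(1, x[:, mo] / 2.0)
        ).astype(np.int8)
    last = ped.generation_indices(ped.n_generations)
    return GenotypeMatrix(
        dosages=x,
        locus_ids=list(founder_G.locus_ids),
        individual_ids=[ped.id[i] for i in last],
    )
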