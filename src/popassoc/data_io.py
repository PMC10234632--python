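"""Core genotype containers and PLINK 1 BED/BIM/FAM readers and writers.

Genotypes are held loci x individuals as reference-allele dosages in
{0, 1, 2}, with an optional boolean missingness mask.  The on-disk format is
the PLINK 1 binary fileset (v1.00 magic ``6c 1b 01``, SNP-major layout,
two bits per genotype); writers transpose/pack as the format demands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

BED_MAGIC = bytes((0x6C, 0x1B, 0x01))

# 2-bit PLINK codes (per byte, lowest bits = first individual):
#   00 -> homozygous A1 (dosage 2), 01 -> missing, 10 -> het, 11 -> hom A2.
_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11}
MISSING = np.int8(-1)


class BedFormatError(ValueError):
    """Raised when a .bed payload violates the PLINK 1 binary encoding."""


@dataclass
class GenotypeMatrix:
    """Loci x individuals dosage matrix with locus/individual identifiers.

    ``dosages[i, j]`` counts the A1 (reference) allele of individual ``j`` at
    locus ``i``; missing entries hold -1 and are flagged in ``missing_mask``.
    """

    dosages: np.ndarray
    locus_ids: list[str]
    individual_ids: list[str]
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2D loci x individuals matrix")
        m, n = self.dosages.shape
        if len(self.locus_ids) != m:
            raise ValueError(f"{len(self.locus_ids)} locus ids for {m} loci")
        if len(self.individual_ids) != n:
            raise ValueError(
                f"{len(self.individual_ids)} individual ids for {n} individuals"
            )
        if self.missing_mask is not None:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.dosages.shape:
                raise ValueError("missing_mask shape mismatch")
        mask = self.missing_mask
        observed = self.dosages if mask is None else self.dosages[~mask]
        if observed.size and not np.isin(observed, (0, 1, 2)).all():
            raise ValueError("non-missing dosages must lie in {0, 1, 2}")

    @property
    def m(self) -> int:
        return self.dosages.shape[0]

    @property
    def n(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Per-locus sample frequency of the counted allele (missing excluded)."""
        x = self.dosages.astype(float)
        if self.missing_mask is not None and self.missing_mask.any():
            x = np.where(self.missing_mask, np.nan, x)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                return np.nanmean(x, axis=1) / 2.0
        return x.mean(axis=1) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)


@dataclass
class SampleAnnotation:
    """Per-individual labels: subpopulation hierarchy, sex, and 1D coordinate."""

    individual_id: list[str]
    subpopulation: list[str] | None = None
    continental: list[str] | None = None
    sex: np.ndarray | None = None  # strings in {female, male, unknown}
    coordinate: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.individual_id)
        for name in ("subpopulation", "continental"):
            lab = getattr(self, name)
            if lab is not None:
                if len(lab) != n:
                    raise ValueError(f"{name} length mismatch")
                if any(not str(v) for v in lab):
                    raise ValueError(f"{name} labels must be non-empty")
        if self.sex is not None:
            self.sex = np.asarray(self.sex, dtype=object)
            if len(self.sex) != n:
                raise ValueError("sex length mismatch")
            bad = set(self.sex) - {"female", "male", "unknown"}
            if bad:
                raise ValueError(f"invalid sex labels: {bad}")
        if self.coordinate is not None:
            self.coordinate = np.asarray(self.coordinate, dtype=float)
            if len(self.coordinate) != n:
                raise ValueError("coordinate length mismatch")

    @property
    def n(self) -> int:
        return len(self.individual_id)

    @classmethod
    def default(cls, n: int, prefix: str = "ind") -> "SampleAnnotation":
        return cls(individual_id=[f"{prefix}{j}" for j in range(n)])

    def to_frame(self) -> pd.DataFrame:
        data = {"individual_id": self.individual_id}
        for name in ("subpopulation", "continental", "sex", "coordinate"):
            v = getattr(self, name)
            if v is not None:
                data[name] = v
        return pd.DataFrame(data)


_SEX_TO_FAM = {"male": 1, "female": 2, "unknown": 0}
_FAM_TO_SEX = {1: "male", 2: "female"}


def bed_byte_count(m: int, n: int) -> int:
    """Total .bed file size in bytes: 3 magic + m * ceil(n / 4) payload."""
    return 3 + m * ((n + 3) // 4)


def write_genotypes(
    G: GenotypeMatrix, ann: SampleAnnotation | None, path_prefix: str | Path
) -> None:
    """Write a PLINK 1 BED/BIM/FAM triplet under ``path_prefix``.

    Simulated data uses synthetic allele labels A (counted, A1) / B and
    sequential 1-based positions on chromosome 1.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    m, n = G.m, G.n
    if ann is None:
        ann = SampleAnnotation(individual_id=list(G.individual_ids))
    if ann.n != n:
        raise ValueError("annotation does not match genotype individuals")

    with open(Path(str(prefix) + ".bim"), "w") as fh:
        for i, lid in enumerate(G.locus_ids):
            fh.write(f"1\t{lid}\t0\t{i + 1}\tA\tB\n")

    with open(Path(str(prefix) + ".fam"), "w") as fh:
        for j, iid in enumerate(G.individual_ids):
            sex = 0
            if ann.sex is not None:
                sex = _SEX_TO_FAM[ann.sex[j]]
            fh.write(f"0\t{iid}\t0\t0\t{sex}\t-9\n")

    codes = np.full((m, n), 0b01, dtype=np.uint8)  # default missing
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[G.dosages == dosage] = code
    if G.missing_mask is not None:
        codes[G.missing_mask] = 0b01
    # pack 4 genotypes per byte, first individual in the lowest bits
    n_bytes = (n + 3) // 4
    padded = np.zeros((m, n_bytes * 4), dtype=np.uint8)
    padded[:, :n] = codes
    quads = padded.reshape(m, n_bytes, 4)
    payload = (
        quads[:, :, 0]
        | (quads[:, :, 1] << 2)
        | (quads[:, :, 2] << 4)
        | (quads[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(Path(str(prefix) + ".bed"), "wb") as fh:
        fh.write(BED_MAGIC)
        fh.write(payload.tobytes())


def read_genotypes(
    path_prefix: str | Path,
) -> tuple[GenotypeMatrix, SampleAnnotation]:
    """Read a PLINK 1 BED/BIM/FAM triplet (SNP-major v1.00 only)."""
    prefix = Path(path_prefix)
    bed, bim, fam = (Path(str(prefix) + s) for s in (".bed", ".bim", ".fam"))
    for path in (bed, bim, fam):
        if not path.exists():
            raise FileNotFoundError(f"missing PLINK file: {path}")

    bim_df = pd.read_csv(
        bim, sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"], dtype={"id": str},
    )
    fam_df = pd.read_csv(
        fam, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"iid": str},
    )
    m, n = len(bim_df), len(fam_df)

    raw = bed.read_bytes()
    if raw[:3] != BED_MAGIC:
        raise BedFormatError(
            f"{bed}: bad magic bytes {raw[:3].hex()} (expected {BED_MAGIC.hex()})"
        )
    expected = bed_byte_count(m, n)
    if len(raw) != expected:
        raise BedFormatError(
            f"{bed}: {len(raw)} bytes, expected {expected} "
            f"(3 magic + {m} loci x {(n + 3) // 4} bytes)"
        )
    n_bytes_per_locus = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(
        m, n_bytes_per_locus
    )
    # unpack: 4 genotypes per byte, lowest bits first
    codes = np.empty((m, payload.shape[1] * 4), dtype=np.uint8)
    codes[:, 0::4] = payload & 0b11
    codes[:, 1::4] = (payload >> 2) & 0b11
    codes[:, 2::4] = (payload >> 4) & 0b11
    codes[:, 3::4] = (payload >> 6) & 0b11
    codes = codes[:, :n]
    dosages = _CODE_TO_DOSAGE[codes]
    mask = dosages == MISSING
    G = GenotypeMatrix(
        dosages=dosages,
        locus_ids=bim_df["id"].tolist(),
        individual_ids=fam_df["iid"].tolist(),
        missing_mask=mask if mask.any() else None,
    )
    ann = SampleAnnotation(
        individual_id=fam_df["iid"].tolist(),
        sex=np.array(
            [_FAM_TO_SEX.get(int(s), "unknown") for s in fam_df["sex"]],
            dtype=object,
        ),
    )
    return G, ann


def filter_loci(G: GenotypeMatrix, maf_min: float = 0.0) -> GenotypeMatrix:
    """Subset to loci with sample MAF >= ``maf_min`` (> 0 if maf_min is 0).

    Useful after pedigree genotype dropping, where drift can fix loci that
    were polymorphic in the founders.
    """
    maf = G.maf()
    keep = maf >= maf_min if maf_min > 0 else maf > 0
    return GenotypeMatrix(
        dosages=G.dosages[keep],
        locus_ids=[l for l, k in zip(G.locus_ids, keep) if k],
        individual_ids=list(G.individual_ids),
        missing_mask=None if G.missing_mask is None else G.missing_mask[keep],
    )


def write_matrix_tsv(
    M: np.ndarray, ids: list[str], path: str | Path
) -> None:
    """Write a square id-labelled matrix (kinship/coancestry) as TSV."""
    pd.DataFrame(M, index=ids, columns=ids).to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_phenotype(
    y: np.ndarray, individual_ids: list[str], path: str | Path
) -> None:
    """Phenotype TSV in FID/IID-keyed layout (FID fixed at 0)."""
    pd.DataFrame(
        {"FID": 0, "IID": individual_ids, "pheno": np.asarray(y, dtype=float)}
    ).to_csv(path, sep="\t", index=False)


def read_phenotype(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", dtype={"IID": str})
    return df.iloc[:, 2].to_numpy(dtype=float), df["IID"].tolist()
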