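"""Core data containers shared across the pipeline.

The unit of genotype data everywhere is the :class:`HaplotypePanel`: a phased
0/1 haplotype matrix (two rows per diploid individual) together with a variant
table carrying coordinates, alleles and allele-frequency bookkeeping.  SNP
arrays are represented as ordered position subsets (:class:`ArrayPanel`) of a
parent panel, mirroring how commercial chips are position lists against a
reference genome build.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ANNOTATION_CLASSES = ("intergenic", "intronic", "updownstream5kb", "missense", "utr")

VARIANT_COLUMNS = ["chrom", "pos", "ref_allele", "alt_allele", "maf", "mac"]


class PanelError(ValueError):
    """Raised when a panel or array violates its structural contract."""


def _as_variant_frame(variants: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise PanelError(f"variant table missing columns: {missing}")
    return variants.reset_index(drop=True)


def compute_maf_mac(haplotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Minor allele frequency and count per column of a 0/1 haplotype matrix."""
    n_hap = haplotypes.shape[0]
    alt = haplotypes.sum(axis=0)
    mac = np.minimum(alt, n_hap - alt).astype(np.int64)
    maf = mac / n_hap
    return maf, mac


@dataclass
class HaplotypePanel:
    """Phased haplotype matrix plus its variant table.

    Parameters
    ----------
    variants
        One row per variant: chrom, pos (1-based), ref_allele, alt_allele,
        maf, mac, and optionally annotation_class.  Positions are strictly
        increasing within each chromosome.
    haplotypes
        ``(2N, M)`` matrix of 0/1 alleles; rows ``2i`` and ``2i+1`` are the
        two haplotypes of individual ``i``.
    individual_ids, breed_labels
        Length-``N`` labels; breed labels tag pure breeds or crosses.
    """

    variants: pd.DataFrame
    haplotypes: np.ndarray
    individual_ids: list[str]
    breed_labels: list[str]
    phased: bool = True
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.variants = _as_variant_frame(self.variants)
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2:
            raise PanelError("haplotypes must be a 2-D matrix")
        if self.haplotypes.shape[0] % 2 != 0:
            raise PanelError("haplotype row count must be even (2 per individual)")
        if self.haplotypes.shape[0] != 2 * len(self.individual_ids):
            raise PanelError("haplotype rows != 2 x individuals")
        if self.haplotypes.shape[1] != len(self.variants):
            raise PanelError("haplotype columns != variant count")
        if len(self.breed_labels) != len(self.individual_ids):
            raise PanelError("breed_labels length mismatch")
        if self.haplotypes.size and self.haplotypes.max(initial=0) > 1:
            raise PanelError("haplotype entries must be 0/1")
        for _, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise PanelError("positions must be strictly increasing within chrom")

    # ------------------------------------------------------------------ views
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    def genotypes(self) -> np.ndarray:
        """Diploid 0/1/2 genotype matrix, ``(N, M)``."""
        return (self.haplotypes[0::2].astype(np.int16) + self.haplotypes[1::2]).astype(np.int8)

    def position_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.variants[["chrom", "pos"]])

    def refresh_frequencies(self) -> None:
        """Recompute maf/mac columns from the haplotype matrix."""
        maf, mac = compute_maf_mac(self.haplotypes)
        self.variants = self.variants.assign(maf=maf, mac=mac)

    # -------------------------------------------------------------- selection
    def take_variants(self, idx: np.ndarray) -> "HaplotypePanel":
        """Panel restricted to the variant columns ``idx`` (order preserved)."""
        idx = np.asarray(idx)
        return replace(
            self,
            variants=self.variants.iloc[idx].reset_index(drop=True),
            haplotypes=self.haplotypes[:, idx],
        )

    def take_individuals(self, which: np.ndarray) -> "HaplotypePanel":
        """Panel restricted to individuals at integer positions ``which``."""
        which = np.asarray(which)
        hap_rows = np.empty(2 * len(which), dtype=np.int64)
        hap_rows[0::2] = 2 * which
        hap_rows[1::2] = 2 * which + 1
        return replace(
            self,
            haplotypes=self.haplotypes[hap_rows],
            individual_ids=[self.individual_ids[i] for i in which],
            breed_labels=[self.breed_labels[i] for i in which],
        )

    def subset_breed(self, breed: str) -> "HaplotypePanel":
        which = np.flatnonzero(np.asarray(self.breed_labels) == breed)
        return self.take_individuals(which)

    def variant_indexer(self) -> dict[tuple, int]:
        return {
            (c, int(p)): i
            for i, (c, p) in enumerate(zip(self.variants["chrom"], self.variants["pos"]))
        }


@dataclass
class ArrayPanel:
    """An ordered set of (chrom, pos) sites emulating an LD/50k/HD SNP chip."""

    name: str
    positions: pd.DataFrame  # columns chrom, pos; sorted within chrom
    target_size: int
    maf_floor: float = 0.0
    scheme: str = ""

    def __post_init__(self) -> None:
        self.positions = self.positions[["chrom", "pos"]].reset_index(drop=True)
        for _, sub in self.positions.groupby("chrom", sort=False):
            if np.any(np.diff(sub["pos"].to_numpy()) <= 0):
                raise PanelError("array positions must be strictly increasing within chrom")

    def __len__(self) -> int:
        return len(self.positions)

    def key_set(self) -> set[tuple]:
        return set(zip(self.positions["chrom"], self.positions["pos"].astype(int)))

    def member_mask(self, variants: pd.DataFrame) -> np.ndarray:
        """Boolean mask over ``variants`` rows that are on this array."""
        keys = self.key_set()
        return np.fromiter(
            ((c, int(p)) in keys for c, p in zip(variants["chrom"], variants["pos"])),
            dtype=bool,
            count=len(variants),
        )

    def is_subset_of(self, other: "ArrayPanel") -> bool:
        return self.key_set() <= other.key_set()


@dataclass
class PhenotypeTable:
    """Adjusted phenotypes with the simulated truth needed for validation."""

    frame: pd.DataFrame  # columns individual_id, y_adj, true_breeding_value
    target_h2: float

    def __post_init__(self) -> None:
        required = {"individual_id", "y_adj", "true_breeding_value"}
        if not required <= set(self.frame.columns):
            raise PanelError(f"phenotype table needs columns {sorted(required)}")
        if self.frame["individual_id"].duplicated().any():
            raise PanelError("duplicate individual_id in phenotype table")

    def y_for(self, ids: list[str]) -> np.ndarray:
        s = self.frame.set_index("individual_id")["y_adj"]
        return s.loc[ids].to_numpy(dtype=float)

    def tbv_for(self, ids: list[str]) -> np.ndarray:
        s = self.frame.set_index("individual_id")["true_breeding_value"]
        return s.loc[ids].to_numpy(dtype=float)
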