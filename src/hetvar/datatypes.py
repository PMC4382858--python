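"""Core in-memory containers shared across the pipeline.

Genotypes are stored as B-allele counts in {0, 1, 2}, with -1 marking a
missing call.  All relationship matrices are dense symmetric ndarrays with an
explicit animal-id index so that phenotype subsetting never relies on
positional luck.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

PEDIGREE_COLUMNS = ["animal", "sire", "dam", "breed", "cohort", "sex"]


@dataclass
class GenotypeMatrix:
    """n animals x m SNPs of B-allele counts, with SNP and animal metadata.

    Parameters
    ----------
    genotypes : int8 ndarray, shape (n, m)
        B-allele counts; ``MISSING`` (-1) marks a missing call.
    snps : DataFrame
        One row per SNP with columns ``snp`` (id), ``chrom``, ``pos``
        (1-based bp), ``a1``, ``a2``.  ``a1`` is the B allele by default.
    animals : list of str
        Animal ids, one per genotype row.
    """

    genotypes: np.ndarray
    snps: pd.DataFrame
    animals: list

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotype matrix must be 2-D")
        n, m = self.genotypes.shape
        if len(self.animals) != n:
            raise ValueError(f"{len(self.animals)} animal ids for {n} genotype rows")
        if len(self.snps) != m:
            raise ValueError(f"{len(self.snps)} SNP records for {m} genotype columns")
        bad = ~np.isin(self.genotypes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotypes must be 0/1/2 or missing (-1)")
        if self.snps["snp"].duplicated().any():
            dups = self.snps.loc[self.snps["snp"].duplicated(), "snp"].tolist()
            raise ValueError(f"duplicated SNP ids: {dups}")

    @property
    def n_animals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def subset_animals(self, ids) -> "GenotypeMatrix":
        pos = {a: i for i, a in enumerate(self.animals)}
        idx = np.array([pos[a] for a in ids], dtype=int)
        return GenotypeMatrix(self.genotypes[idx], self.snps.copy(), list(ids))

    def subset_snps(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(self.genotypes[:, mask],
                              self.snps[mask].reset_index(drop=True),
                              list(self.animals))

    def drop_chromosomes(self, chroms=("X",)) -> "GenotypeMatrix":
        """Exclude whole chromosomes (default: X, whose dosage model differs)."""
        return self.subset_snps(~self.snps["chrom"].astype(str).isin(chroms))


@dataclass
class RelationshipMatrix:
    """Symmetric n x n covariance-structure matrix (GRM, DRM or pedigree A)."""

    values: np.ndarray
    animals: list
    kind: str  # "GRM" | "DRM" | "A" | custom label

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.animals)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape does not match animal ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("relationship matrix is not symmetric")

    def subset(self, ids) -> "RelationshipMatrix":
        """Select rows/columns for the given animals (phenotype subsetting)."""
        pos = {a: i for i, a in enumerate(self.animals)}
        idx = np.array([pos[a] for a in ids], dtype=int)
        return RelationshipMatrix(self.values[np.ix_(idx, idx)], list(ids), self.kind)


@dataclass
class TraitTruth:
    """Ground-truth genetic architecture used by the phenotype simulator.

    ``causal_additive`` holds (snp index, alpha) pairs in trait units per B
    allele; ``causal_dominance`` holds (snp index, delta) heterozygote
    deviations; ``causal_epistatic`` holds (lead index, partner index, m)
    additive-by-additive interactions on the 0/1/2 dosage scale.
    """

    causal_additive: list = field(default_factory=list)
    causal_dominance: list = field(default_factory=list)
    causal_epistatic: list = field(default_factory=list)
    polygenic_var: float = 0.0
    residual_var: float = 1.0
    dominance_direction: int = 0

    def validate(self, n_snps: int) -> None:
        if self.polygenic_var < 0 or self.residual_var < 0:
            raise ValueError("variances must be non-negative")
        add = [i for i, _ in self.causal_additive]
        dom = [i for i, _ in self.causal_dominance]
        epi = [(j, i) for j, i, _ in self.causal_epistatic]
        for i in add + dom + [k for pair in epi for k in pair]:
            if not 0 <= i < n_snps:
                raise ValueError(f"causal SNP index {i} out of range (m={n_snps})")
        if len(set(add)) != len(add) or len(set(dom)) != len(dom):
            raise ValueError("duplicate causal assignment")
        if len(set(epi)) != len(epi):
            raise ValueError("duplicate epistatic pair")
        if self.dominance_direction not in (-1, 0, 1):
            raise ValueError("dominance_direction must be -1, 0 or +1")


def as_pedigree_frame(ped: pd.DataFrame) -> pd.DataFrame:
    """Normalise a pedigree table: required columns, parents before offspring.

    Sire/dam of founders are NA.  Raises on cycles (an animal that is its own
    ancestor).
    """
    missing_cols = [c for c in ("animal", "sire", "dam") if c not in ped.columns]
    if missing_cols:
        raise ValueError(f"pedigree missing columns: {missing_cols}")
    ped = ped.copy()
    for c in PEDIGREE_COLUMNS:
        if c not in ped.columns:
            ped[c] = pd.NA
    # topological check via iterative depth computation
    parents = {
        r.animal: (r.sire if pd.notna(r.sire) else None, r.dam if pd.notna(r.dam) else None)
        for r in ped.itertuples()
    }
    state: dict = {}

    def depth(a, stack):
        if a is None or a not in parents:
            return 0
        if a in stack:
            raise ValueError(f"pedigree cycle involving {a}")
        if a in state:
            return state[a]
        stack.add(a)
        s, d = parents[a]
        out = 1 + max(depth(s, stack), depth(d, stack))
        stack.discard(a)
        state[a] = out
        return out

    ped["_depth"] = [depth(a, set()) for a in ped["animal"]]
    ped = ped.sort_values(["_depth", "animal"], kind="stable").drop(columns="_depth")
    return ped.reset_index(drop=True)
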