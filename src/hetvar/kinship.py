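"""Additive/dominance SNP codings and relationship matrices.

Allele frequencies are always computed over the whole combined dataset, so a
multi-breed panel is treated as descending from one base population; within
that base, genotype classes AA/AB/BB at a SNP with B-allele frequency p are
coded

* additively  as  T = -2p/sqrt(2pq), (q-p)/sqrt(2pq), 2q/sqrt(2pq)
  (equivalently (x - 2p)/sqrt(2pq) for dosage x), and
* for dominance as H = -p/q, +1, -q/p.

Under Hardy-Weinberg weights these codings satisfy E(H)=0, E(H^2)=1 and
E(HT)=0: the dominance contrast is orthogonal to allele substitution, so
GRM = TT'/m and DRM = HH'/m partition genetic covariance cleanly and the
variance attached to the DRM is classical dominance variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix, RelationshipMatrix, as_pedigree_frame


@dataclass
class AlleleFrequencies:
    """Per-SNP B-allele frequencies with retention flags.

    ``retained`` marks SNPs whose pooled MAF clears ``maf_floor``; SNPs at or
    beyond the boundary (p in {0,1}, where the 1/(2pq) weight blows up) and
    SNPs with zero called genotypes are excluded from both codings.
    """

    p: np.ndarray
    n_called: np.ndarray
    retained: np.ndarray
    maf_floor: float

    @property
    def q(self) -> np.ndarray:
        return 1.0 - self.p


@dataclass
class CodingMatrix:
    """n x m_retained real coding matrix; ``kind`` is ``"T"`` or ``"H"``."""

    values: np.ndarray
    kind: str
    snp_indices: np.ndarray  # columns of the source GenotypeMatrix retained


def allele_frequencies(G: GenotypeMatrix, maf_floor: float | None = None) -> AlleleFrequencies:
    """B-allele frequency p = (2 n_BB + n_AB) / (2 n_called) per SNP.

    ``maf_floor`` defaults to 1/(2n): rarer SNPs make the frequency-weighted
    codings numerically explosive and carry no estimable dominance contrast.
    """
    x = G.genotypes
    called = x != MISSING
    n_called = called.sum(axis=0)
    b_alleles = np.where(called, x, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_called > 0, b_alleles / (2.0 * np.maximum(n_called, 1)), np.nan)
    if maf_floor is None:
        maf_floor = 1.0 / (2.0 * G.n_animals)
    maf = np.minimum(p, 1.0 - p)
    retained = (n_called > 0) & (maf >= maf_floor)
    return AlleleFrequencies(p=p, n_called=n_called, retained=retained, maf_floor=maf_floor)


def _retained(freqs: AlleleFrequencies):
    idx = np.flatnonzero(freqs.retained)
    if idx.size == 0:
        raise ValueError("no SNPs retained after frequency filtering")
    return idx, freqs.p[idx]


def additive_coding(
    G: GenotypeMatrix, freqs: AlleleFrequencies, strict_missing: bool = False
) -> CodingMatrix:
    """Standardised additive coding T = (x - 2p) / sqrt(2pq).

    Missing calls are mean-imputed (coded 0, i.e. dosage 2p) unless
    ``strict_missing`` is set, in which case they raise.
    """
    idx, p = _retained(freqs)
    x = G.genotypes[:, idx].astype(float)
    miss = x == MISSING
    if strict_missing and miss.any():
        raise ValueError("missing genotypes present and strict mode requested")
    x[miss] = 2.0 * np.broadcast_to(p, x.shape)[miss]
    T = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    return CodingMatrix(T, "T", idx)


def dominance_coding(
    G: GenotypeMatrix, freqs: AlleleFrequencies, strict_missing: bool = False
) -> CodingMatrix:
    """Frequency-weighted dominance coding H: AA -> -p/q, AB -> +1, BB -> -q/p.

    Missing calls are imputed at the HWE class average (which is 0, the
    expectation of H over genotype frequencies q^2 : 2pq : p^2) unless
    ``strict_missing`` is set.
    """
    idx, p = _retained(freqs)
    q = 1.0 - p
    x = G.genotypes[:, idx]
    miss = x == MISSING
    if strict_missing and miss.any():
        raise ValueError("missing genotypes present and strict mode requested")
    H = np.empty(x.shape, dtype=float)
    codes = np.stack([-p / q, np.ones_like(p), -q / p])  # rows: AA, AB, BB
    for g in (0, 1, 2):
        H[x == g] = np.broadcast_to(codes[g], x.shape)[x == g]
    H[miss] = 0.0
    return CodingMatrix(H, "H", idx)


def grm(T: CodingMatrix) -> np.ndarray:
    """Genomic relationship matrix TT'/m over retained SNPs."""
    if T.kind != "T":
        raise ValueError("grm expects the additive coding")
    m = T.values.shape[1]
    if m == 0:
        raise ValueError("empty SNP panel")
    return T.values @ T.values.T / m


def drm(H: CodingMatrix) -> np.ndarray:
    """Dominance relationship matrix HH'/m over retained SNPs."""
    if H.kind != "H":
        raise ValueError("drm expects the dominance coding")
    m = H.values.shape[1]
    if m == 0:
        raise ValueError("empty SNP panel")
    return H.values @ H.values.T / m


def genomic_matrices(
    G: GenotypeMatrix, maf_floor: float | None = None, strict_missing: bool = False
) -> tuple[RelationshipMatrix, RelationshipMatrix, AlleleFrequencies]:
    """Convenience: frequencies, then (GRM, DRM) as RelationshipMatrix objects."""
    freqs = allele_frequencies(G, maf_floor=maf_floor)
    T = additive_coding(G, freqs, strict_missing=strict_missing)
    H = dominance_coding(G, freqs, strict_missing=strict_missing)
    g = RelationshipMatrix(grm(T), list(G.animals), "GRM")
    d = RelationshipMatrix(drm(H), list(G.animals), "DRM")
    return g, d, freqs


def vitezica_drm(G: GenotypeMatrix, freqs: AlleleFrequencies) -> np.ndarray:
    """Unweighted (Vitezica-style) DRM, offered only as a labelled alternative.

    Codes AA/AB/BB as -2p^2, 2pq, -2q^2 and divides by sum over SNPs of
    (2pq)^2 rather than weighting each SNP by 1/(2pq).
    """
    idx, p = _retained(freqs)
    q = 1.0 - p
    x = G.genotypes[:, idx]
    W = np.empty(x.shape, dtype=float)
    codes = np.stack([-2 * p**2, 2 * p * q, -2 * q**2])
    for g in (0, 1, 2):
        W[x == g] = np.broadcast_to(codes[g], x.shape)[x == g]
    W[x == MISSING] = 0.0
    return W @ W.T / np.sum((2 * p * q) ** 2)


def heterozygosity(G: GenotypeMatrix, freqs: AlleleFrequencies | None = None) -> np.ndarray:
    """Per-animal mean heterozygosity: fraction of retained SNPs called AB."""
    x = G.genotypes
    if freqs is not None:
        x = x[:, freqs.retained]
    called = x != MISSING
    n_called = called.sum(axis=1)
    het = (x == 1).sum(axis=1)
    return np.where(n_called > 0, het / np.maximum(n_called, 1), np.nan)


def pedigree_A(
    ped: pd.DataFrame, animals=None, max_depth: int = 5
) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    ``animals`` selects the focal individuals (default: every animal in the
    pedigree); ancestors more than ``max_depth`` generations above any focal
    animal are pruned before the recursion, so their links are treated as
    unknown.  Diagonals are 1 + F with F the inbreeding coefficient.
    """
    ped = as_pedigree_frame(ped)
    parent = {
        r.animal: (r.sire if pd.notna(r.sire) else None, r.dam if pd.notna(r.dam) else None)
        for r in ped.itertuples()
    }
    focal = list(ped["animal"]) if animals is None else list(animals)
    # breadth-first ancestor walk, bounded at max_depth generations
    keep = set(focal)
    frontier = set(focal)
    for _ in range(max_depth):
        nxt = set()
        for a in frontier:
            for par in parent.get(a, (None, None)):
                if par is not None and par in parent and par not in keep:
                    nxt.add(par)
        keep |= nxt
        frontier = nxt
    ped = ped[ped["animal"].isin(keep)].reset_index(drop=True)
    order = list(ped["animal"])
    pos = {a: i for i, a in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for i, a in enumerate(order):
        s, d = parent[a]
        si = pos.get(s) if s in keep else None
        di = pos.get(d) if d in keep else None
        A[i, i] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)
        for j in range(i):
            val = 0.0
            if si is not None:
                val += 0.5 * A[j, si]
            if di is not None:
                val += 0.5 * A[j, di]
            A[i, j] = A[j, i] = val
    sel = np.array([pos[a] for a in focal])
    return RelationshipMatrix(A[np.ix_(sel, sel)], focal, "A")
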