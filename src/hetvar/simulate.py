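"""Synthetic multi-breed genotypes, sire-family pedigrees and phenotypes.

The generator emulates the structure of a multi-breed beef-cattle panel:
several breeds with breed-specific allele frequencies, paternal half-sib
families produced by gene-dropping from founder sires and dams, biallelic
SNPs in approximate Hardy-Weinberg equilibrium within breed, and traits built
from additive dosage effects, (optionally directional) dominance deviations
of heterozygotes, additive-by-additive interactions between designated lead
SNPs and partner SNPs, a pedigree-correlated polygenic term, and i.i.d.
residuals.

All randomness flows from one integer seed: each operation derives an
independent child stream from ``numpy.random.SeedSequence(seed)`` so that,
for example, re-running phenotype simulation does not disturb genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, TraitTruth, as_pedigree_frame
from .kinship import AlleleFrequencies, allele_frequencies


@dataclass
class SimConfig:
    """Study-design knobs for the genotype simulator.

    ``n_sires_per_breed = 0`` produces an unrelated founder panel (no family
    structure); otherwise each breed consists of paternal half-sib families:
    ``animals_per_breed`` offspring split evenly over the sires, each
    offspring from its own unrelated dam.

    ``allele_freq_spec`` is either a ``(a, b)`` tuple of Beta parameters —
    founder frequencies drawn per breed from Beta(a, b) rescaled into
    [maf_floor, 1 - maf_floor] — or a list of per-breed frequency vectors of
    length ``n_snps``.  The default Beta(2, 2) gives a hump-shaped spectrum
    with estimable dominance at every SNP.
    """

    n_breeds: int = 1
    animals_per_breed: int = 500
    n_sires_per_breed: int = 25
    n_snps: int = 1000
    allele_freq_spec: object = (2.0, 2.0)
    maf_floor: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_breeds < 1 or self.animals_per_breed < 1 or self.n_snps < 1:
            raise ValueError("n_breeds, animals_per_breed and n_snps must be >= 1")
        if self.n_sires_per_breed < 0:
            raise ValueError("n_sires_per_breed must be >= 0")
        if not 0.0 < self.maf_floor < 0.5:
            raise ValueError("maf_floor must lie in (0, 0.5)")


def _breed_frequencies(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    spec = config.allele_freq_spec
    if isinstance(spec, tuple) and len(spec) == 2:
        a, b = spec
        raw = rng.beta(a, b, size=(config.n_breeds, config.n_snps))
        lo, hi = config.maf_floor, 1.0 - config.maf_floor
        return lo + raw * (hi - lo)
    freqs = np.asarray(spec, dtype=float)
    if freqs.shape != (config.n_breeds, config.n_snps):
        raise ValueError("explicit frequencies must be (n_breeds, n_snps)")
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("frequencies must lie in (0, 1)")
    return freqs


def _hwe_genotypes(p: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    return (rng.random((n, p.size)) < p).astype(np.int8) + (
        rng.random((n, p.size)) < p
    ).astype(np.int8)


def _transmit(parent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per SNP: homozygotes transmit their allele, hets a coin flip."""
    coin = (rng.random(parent.shape) < 0.5).astype(np.int8)
    return np.where(parent == 1, coin, (parent // 2).astype(np.int8))


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Gene-drop genotypes for a multi-breed half-sib design.

    Returns the genotypes of the study animals (offspring, or founders when
    ``n_sires_per_breed == 0``) and the full pedigree including founder sires
    and dams.  SNPs whose pooled MAF across the study animals falls below
    ``config.maf_floor`` are redrawn (fresh founder frequency and genotypes)
    until every SNP clears the floor.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed).spawn(2)
    rng_freq, rng_geno = (np.random.default_rng(s) for s in ss)
    freqs = _breed_frequencies(config, rng_freq)

    def drop_breed(b: int, snp_sel: np.ndarray):
        """Simulate one breed at the selected SNP columns; returns study rows
        plus sire genotype bookkeeping implicit in ids."""
        p = freqs[b, snp_sel]
        n_off = config.animals_per_breed
        if config.n_sires_per_breed == 0:
            return _hwe_genotypes(p, n_off, rng_geno), None
        n_sires = config.n_sires_per_breed
        sires = _hwe_genotypes(p, n_sires, rng_geno)
        dams = _hwe_genotypes(p, n_off, rng_geno)
        sire_of = np.arange(n_off) % n_sires
        off = _transmit(sires[sire_of], rng_geno) + _transmit(dams, rng_geno)
        return off, sire_of

    all_idx = np.arange(config.n_snps)
    geno_parts = [np.zeros((config.animals_per_breed, config.n_snps), dtype=np.int8)
                  for _ in range(config.n_breeds)]
    sire_maps = [None] * config.n_breeds
    pending = all_idx
    for attempt in range(100):
        for b in range(config.n_breeds):
            g, sire_of = drop_breed(b, pending)
            geno_parts[b][:, pending] = g
            if attempt == 0:
                sire_maps[b] = sire_of
        pooled = np.concatenate([gp[:, pending] for gp in geno_parts], axis=0)
        p_hat = pooled.mean(axis=0) / 2.0
        maf = np.minimum(p_hat, 1 - p_hat)
        bad = maf < config.maf_floor
        if not bad.any():
            break
        # redraw founder frequencies (Beta spec only) and genotypes for
        # failing SNPs; explicit-frequency panels just re-drop genotypes
        failing = pending[bad]
        if isinstance(config.allele_freq_spec, tuple):
            a, bpar = config.allele_freq_spec
            freqs[:, failing] = config.maf_floor + rng_freq.beta(
                a, bpar, size=(config.n_breeds, failing.size)
            ) * (1 - 2 * config.maf_floor)
        pending = failing
    else:
        raise RuntimeError("could not satisfy the MAF floor after 100 resampling rounds")

    rows = []
    animals = []
    genos = []
    for b in range(config.n_breeds):
        breed = f"B{b + 1}"
        n_off = config.animals_per_breed
        if config.n_sires_per_breed == 0:
            for i in range(n_off):
                aid = f"{breed}_F{i + 1}"
                animals.append(aid)
                rows.append((aid, None, None, breed, "founder", "U"))
            genos.append(geno_parts[b])
            continue
        for s in range(config.n_sires_per_breed):
            rows.append((f"{breed}_S{s + 1}", None, None, breed, "founder", "M"))
        for i in range(n_off):
            rows.append((f"{breed}_D{i + 1}", None, None, breed, "founder", "F"))
        for i in range(n_off):
            aid = f"{breed}_O{i + 1}"
            animals.append(aid)
            rows.append((aid, f"{breed}_S{sire_maps[b][i] + 1}", f"{breed}_D{i + 1}",
                         breed, "offspring", "U"))
        genos.append(geno_parts[b])

    ped = pd.DataFrame(rows, columns=["animal", "sire", "dam", "breed", "cohort", "sex"])
    snps = pd.DataFrame({
        "snp": [f"SNP{i + 1}" for i in range(config.n_snps)],
        "chrom": (np.arange(config.n_snps) % 29 + 1).astype(str),
        "pos": np.arange(config.n_snps) * 1000 + 1,
        "a1": "B",
        "a2": "A",
    })
    G = GenotypeMatrix(np.concatenate(genos, axis=0), snps, animals)
    return G, as_pedigree_frame(ped)


def _polygenic_values(ped: pd.DataFrame, sigma2: float, rng: np.random.Generator) -> dict:
    """Breeding values by gene-dropping down the pedigree: founders N(0, s2),
    offspring mid-parent plus Mendelian-sampling N(0, s2/2)."""
    ped = as_pedigree_frame(ped)
    a: dict = {}
    sd = np.sqrt(sigma2)
    for r in ped.itertuples():
        s = a.get(r.sire) if pd.notna(r.sire) else None
        d = a.get(r.dam) if pd.notna(r.dam) else None
        if s is None and d is None:
            a[r.animal] = rng.normal(0.0, sd)
        else:
            mid = 0.5 * ((s if s is not None else 0.0) + (d if d is not None else 0.0))
            # Mendelian-sampling variance tops the offspring back up to s2;
            # an unknown parent's gamete counts as a founder draw
            k_known = (s is not None) + (d is not None)
            ms_var = sigma2 * (1.0 - 0.25 * k_known)
            a[r.animal] = mid + rng.normal(0.0, np.sqrt(ms_var))
    return a


def simulate_phenotypes(
    G: GenotypeMatrix,
    ped: pd.DataFrame,
    truth: TraitTruth,
    seed: int = 0,
    freqs: AlleleFrequencies | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Phenotypes y = sum s_i alpha_i + sum w_i delta_i + sum (l_j o s_i) m_ji
    + polygenic + residual, plus a realized per-animal component table.

    The component table splits each causal SNP's contribution into its
    statistical additive part (allele-substitution, including the (q - p)
    delta term a heterozygote effect induces) and its dominance deviation
    (the 2pq-scaled orthogonal heterozygosity contrast), both at pooled
    allele frequencies, so ``components.var()`` is directly comparable with
    fitted variance components.
    """
    truth.validate(G.n_snps)
    ss = np.random.SeedSequence(seed).spawn(2)
    rng_poly, rng_resid = (np.random.default_rng(s) for s in ss)
    n = G.n_animals
    x = G.genotypes.astype(float)
    if freqs is None:
        freqs = allele_frequencies(G, maf_floor=0.0)
    p = freqs.p
    q = 1.0 - p

    add = np.zeros(n)
    dom = np.zeros(n)
    for i, alpha in truth.causal_additive:
        add += alpha * x[:, i]
    for i, delta in truth.causal_dominance:
        # allele-substitution part of a heterozygote effect: delta*(q-p) per B allele
        add += delta * (2 * p[i] * q[i] + (q[i] - p[i]) * x[:, i])
        dd = np.select([x[:, i] == 0, x[:, i] == 1, x[:, i] == 2],
                       [-2 * p[i] ** 2, 2 * p[i] * q[i], -2 * q[i] ** 2])
        dom += delta * dd  # additive + dominance parts reassemble delta * w exactly
    epi = np.zeros(n)
    for j, i, m in truth.causal_epistatic:
        epi += m * x[:, j] * x[:, i]

    if truth.polygenic_var > 0:
        avals = _polygenic_values(ped, truth.polygenic_var, rng_poly)
        poly = np.array([avals.get(a, 0.0) for a in G.animals])
    else:
        poly = np.zeros(n)
    resid = rng_resid.normal(0.0, np.sqrt(truth.residual_var), size=n) \
        if truth.residual_var > 0 else np.zeros(n)

    y = add + dom + epi + poly + resid
    components = pd.DataFrame({
        "additive": add, "dominance": dom, "epistatic": epi,
        "polygenic": poly, "residual": resid, "total": y,
    }, index=pd.Index(G.animals, name="animal"))
    return y, components


def truth_from_fractions(
    G: GenotypeMatrix,
    va_frac: float,
    vd_frac: float,
    vp: float = 1.0,
    n_causal: int | None = None,
    dominance_direction: int = 0,
    polygenic_frac: float = 0.0,
    seed: int = 0,
    freqs: AlleleFrequencies | None = None,
    scale: str = "realized",
) -> TraitTruth:
    """Build a TraitTruth whose additive/dominance variance fractions hit the
    requested targets on this genotype sample.

    Effects are drawn i.i.d. on the standardized T/H scales (the scale on
    which GRM/DRM-based models assume exchangeable SNP effects) and converted
    to dosage-scale (alpha, delta) pairs.  With ``scale="realized"`` each
    effect class is then rescaled so the realized sample variances equal
    ``va_frac * vp`` and ``vd_frac * vp`` exactly.  With ``scale="model"``
    the standardized effects keep variances ``va_frac * vp / m`` and
    ``vd_frac * vp / m`` untouched, so the base-population parameters
    sigma_g^2 and sigma_d^2 of a GRM/DRM variance-component model equal the
    targets exactly while the realized sample variances fluctuate — the
    appropriate ground truth when checking estimator bias.  Residual variance
    absorbs the remainder of ``vp``.
    """
    if va_frac + vd_frac + polygenic_frac > 1.0 + 1e-12:
        raise ValueError("variance fractions exceed 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    if freqs is None:
        freqs = allele_frequencies(G, maf_floor=0.0)
    m = G.n_snps
    idx = np.arange(m) if n_causal is None else np.sort(
        rng.choice(m, size=min(n_causal, m), replace=False))
    p, q = freqs.p[idx], 1 - freqs.p[idx]
    x = G.genotypes[:, idx].astype(float)

    u = rng.normal(size=idx.size)
    v = rng.normal(size=idx.size)
    if dominance_direction != 0:
        v = dominance_direction * np.abs(v)

    if scale == "model":
        # sigma_g^2 = va, sigma_d^2 = vd on the relationship-matrix scale:
        # y picks up T u + H v with u, v i.i.d.; H = const + x (p-q)/(2pq)
        # + w/(2pq), so the dosage-scale pair is recovered exactly below
        u = u * np.sqrt(va_frac * vp / idx.size)
        v = v * np.sqrt(vd_frac * vp / idx.size)
        alpha = u / np.sqrt(2 * p * q) + v * (p - q) / (2 * p * q)
        delta = v / (2 * p * q)
        vg = (va_frac + vd_frac + polygenic_frac) * vp
        return TraitTruth(
            causal_additive=[(int(i), float(a)) for i, a in zip(idx, alpha)],
            causal_dominance=[(int(i), float(d)) for i, d in zip(idx, delta)],
            causal_epistatic=[],
            polygenic_var=polygenic_frac * vp,
            residual_var=max(vp - vg, 0.0),
            dominance_direction=dominance_direction,
        )
    if scale != "realized":
        raise ValueError("scale must be 'realized' or 'model'")
    alpha = u / np.sqrt(2 * p * q)
    delta = v / (2 * p * q)

    # realized statistical components at pooled frequencies
    add = x @ (alpha + delta * (q - p))
    dd = np.select(
        [x == 0, x == 1, x == 2],
        [np.broadcast_to(-2 * p**2, x.shape), np.broadcast_to(2 * p * q, x.shape),
         np.broadcast_to(-2 * q**2, x.shape)],
    )
    dom = dd @ delta
    sd_dom = dom.std(ddof=1)
    c_d = np.sqrt(vd_frac * vp) / sd_dom if sd_dom > 0 and vd_frac > 0 else 0.0
    delta = delta * c_d
    # After fixing delta, its allele-substitution side effect is mostly
    # cancelled by a least-squares alpha correction (directional dominance
    # would otherwise force more additive variance than a small va target
    # allows); the remaining alpha scale then solves a quadratic.
    add_from_delta = x @ (delta * (q - p))
    resid_add = add_from_delta - add_from_delta.mean()
    xc = x - x.mean(axis=0)
    alpha_corr = np.linalg.lstsq(xc, -resid_add, rcond=None)[0] if vd_frac > 0 else np.zeros_like(alpha)
    r = resid_add + xc @ alpha_corr
    a0 = xc @ alpha
    va_target = va_frac * vp
    A = a0 @ a0
    B = 2 * (a0 @ r)
    C = r @ r - va_target * (x.shape[0] - 1)
    disc = B * B - 4 * A * C
    if disc < 0 or A == 0:
        raise ValueError("additive target unreachable given the dominance draw")
    c_a = (-B + np.sqrt(disc)) / (2 * A)
    alpha = alpha * c_a + alpha_corr

    vg = (va_frac + vd_frac + polygenic_frac) * vp
    return TraitTruth(
        causal_additive=[(int(i), float(a)) for i, a in zip(idx, alpha)],
        causal_dominance=[(int(i), float(d)) for i, d in zip(idx, delta)],
        causal_epistatic=[],
        polygenic_var=polygenic_frac * vp,
        residual_var=max(vp - vg, 0.0),
        dominance_direction=dominance_direction,
    )
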