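"""Readers and writers: PLINK binary genotypes, dosage TSV, relationship
matrices, phenotype/pedigree tables and YAML pipeline configuration.

The PLINK .bed codec implements the SNP-major 2-bit format directly: magic
bytes 0x6c 0x1b 0x01, then ceil(n/4) bytes per SNP, first sample in the two
lowest-order bits.  Bit codes: 00 homozygous A1, 10 heterozygous, 11
homozygous A2, 01 missing.  By default A1 is counted as the B allele, so
00 -> 2, 10 -> 1, 11 -> 0; pass ``b_allele="a2"`` to flip the orientation.
Malformed files are rejected (never reinterpreted) with the failing byte
offset in the message.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import MISSING, GenotypeMatrix, RelationshipMatrix, as_pedigree_frame

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# lookup: 2-bit plink code -> B-allele count with A1 counted (01 = missing)
_CODE_TO_COUNT = np.array([2, MISSING, 1, 0], dtype=np.int8)
_COUNT_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def read_plink(prefix: str | Path, b_allele: str = "a1") -> GenotypeMatrix:
    """Read a .bed/.bim/.fam triple into a GenotypeMatrix."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"], dtype=str,
    )
    if bim["snp"].duplicated().any():
        dups = bim.loc[bim["snp"].duplicated(), "snp"].tolist()
        raise ValueError(f"duplicated SNP ids in .bim: {dups}")
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f".bed magic bytes wrong at offset 0: {raw[:3].hex()}")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise ValueError(
            f".bed truncated or oversized: expected {expected} bytes, "
            f"got {len(raw)} (failure at offset {min(len(raw), expected)})"
        )
    data = np.frombuffer(raw[3:], dtype=np.uint8).reshape(m, bytes_per_snp)
    # unpack 2-bit codes, sample-major within byte from the low bits
    codes = np.stack([(data >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=-1)
    codes = codes.reshape(m, -1)[:, :n]
    geno = _CODE_TO_COUNT[codes].T.copy()  # (n, m)
    if b_allele == "a2":
        called = geno != MISSING
        geno[called] = 2 - geno[called]
    elif b_allele != "a1":
        raise ValueError("b_allele must be 'a1' or 'a2'")
    snps = bim[["snp", "chrom", "pos", "a1", "a2"]].copy()
    return GenotypeMatrix(geno, snps, fam["iid"].tolist())


def write_plink(G: GenotypeMatrix, prefix: str | Path, ped: pd.DataFrame | None = None) -> None:
    """Write a GenotypeMatrix as .bed/.bim/.fam (A1 = B allele)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    s = G.snps
    bim = pd.DataFrame({
        "chrom": s["chrom"], "snp": s["snp"], "cm": 0, "pos": s["pos"],
        "a1": s.get("a1", "B"), "a2": s.get("a2", "A"),
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    if ped is not None:
        ped = ped.set_index("animal")
        rows = []
        for a in G.animals:
            r = ped.loc[a] if a in ped.index else None
            rows.append((
                r["breed"] if r is not None and pd.notna(r["breed"]) else "0", a,
                r["sire"] if r is not None and pd.notna(r["sire"]) else "0",
                r["dam"] if r is not None and pd.notna(r["dam"]) else "0",
                "0", "-9",
            ))
    else:
        rows = [("0", a, "0", "0", "0", "-9") for a in G.animals]
    pd.DataFrame(rows).to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    n, m = G.n_animals, G.n_snps
    bytes_per_snp = (n + 3) // 4
    code_lut = np.zeros(256, dtype=np.uint8)
    for cnt, code in _COUNT_TO_CODE.items():
        code_lut[np.int8(cnt).view(np.uint8)] = code
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)  # pad bits are 00
    padded[:, :n] = code_lut[G.genotypes.T.astype(np.uint8)]
    packed = (
        padded.reshape(m, bytes_per_snp, 4).astype(np.uint16)
        * np.array([1, 4, 16, 64], dtype=np.uint16)
    ).sum(axis=-1).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    """Plain dosage table: columns snp, chrom, pos, a1, a2, then one column
    per animal holding 0/1/2 (NA = missing)."""
    meta_cols = ["snp", "chrom", "pos", "a1", "a2"]
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header[:5] != meta_cols:
        raise ValueError(f"dosage table must start with columns {meta_cols}")
    animals = header[5:]  # parsed by hand: animal ids may shadow meta names
    df = pd.read_csv(path, sep="\t", skiprows=1, header=None,
                     names=[f"c{i}" for i in range(len(header))],
                     dtype={"c0": str, "c1": str})
    df.columns = meta_cols + [f"animal_{i}" for i in range(len(animals))]
    geno = df.iloc[:, 5:].to_numpy(dtype=float).T
    geno = np.where(np.isnan(geno), MISSING, geno).astype(np.int8)
    return GenotypeMatrix(geno, df[meta_cols].copy(), animals)


def write_dosage_tsv(G: GenotypeMatrix, path: str | Path) -> None:
    out = G.snps[["snp", "chrom", "pos", "a1", "a2"]].copy()
    geno = G.genotypes.astype(object)
    geno[geno == MISSING] = np.nan
    cols = pd.DataFrame({a: geno[i] for i, a in enumerate(G.animals)})
    pd.concat([out.reset_index(drop=True), cols], axis=1).to_csv(
        path, sep="\t", index=False, na_rep="NA")


def write_relationship_long(K: RelationshipMatrix, path: str | Path, header: str = "") -> None:
    """Lower-triangle long format: id_i, id_j, value (tab-separated)."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("id_i\tid_j\tvalue\n")
        for i, ai in enumerate(K.animals):
            for j in range(i + 1):
                fh.write(f"{ai}\t{K.animals[j]}\t{K.values[i, j]:.10g}\n")


def read_relationship_long(path: str | Path, kind: str = "GRM") -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"id_i": str, "id_j": str})
    animals = list(dict.fromkeys(df["id_i"].tolist() + df["id_j"].tolist()))
    pos = {a: i for i, a in enumerate(animals)}
    n = len(animals)
    V = np.zeros((n, n))
    for r in df.itertuples():
        i, j = pos[r.id_i], pos[r.id_j]
        V[i, j] = V[j, i] = r.value
    return RelationshipMatrix(V, animals, kind)


def write_gcta_grm(K: RelationshipMatrix, prefix: str | Path, n_snps: int = 0) -> None:
    """GCTA-compatible dense layout: .grm.bin (float32 lower triangle),
    .grm.N.bin (per-pair SNP counts) and .grm.id sidecar."""
    prefix = Path(prefix)
    tri = np.concatenate([K.values[i, : i + 1] for i in range(len(K.animals))])
    tri.astype("<f4").tofile(f"{prefix}.grm.bin")
    np.full(tri.size, n_snps, dtype="<f4").tofile(f"{prefix}.grm.N.bin")
    pd.DataFrame({"fid": K.animals, "iid": K.animals}).to_csv(
        f"{prefix}.grm.id", sep="\t", header=False, index=False
    )


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def output_header(seed, cfg: dict | None = None) -> str:
    from . import __version__

    h = config_hash(cfg) if cfg else "none"
    return f"hetvar v{__version__} seed={seed} config={h}"


def write_table(df: pd.DataFrame, path: str | Path, seed=None, cfg: dict | None = None) -> None:
    """TSV with a provenance comment header (version, seed, config hash)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# {output_header(seed, cfg)}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"animal": str})
    if "animal" not in df.columns:
        raise ValueError("phenotype table needs an 'animal' column")
    return df


def read_pedigree(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return as_pedigree_frame(df)


def read_snp_list(path: str | Path) -> list:
    return [ln.strip() for ln in Path(path).read_text().splitlines()
            if ln.strip() and not ln.startswith("#")]
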