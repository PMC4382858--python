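"""End-to-end driver: simulate (optional) -> kinship -> variance components
-> dominance GWAS -> epistasis -> sire-family cross-validation.

Every stage logs what went in (seed, animal and SNP counts, SNPs retained or
dropped) and writes plain-text tables stamped with the package version, the
seed and a config hash, so reruns at a fixed seed are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .crossval import accuracy_by_breed, cv_predict, sign_concordance, sire_family_folds
from .datatypes import GenotypeMatrix, RelationshipMatrix, TraitTruth
from .epistasis import scan_all_leads
from .gwas import fit_null_background, scan
from .kinship import genomic_matrices, heterozygosity, pedigree_A
from .reml import ModelSpec, build_spec, lrt_dominance, reml_fit
from .simulate import SimConfig, simulate_genotypes, simulate_phenotypes, truth_from_fractions

log = logging.getLogger("hetvar")

DEFAULTS = {
    "seed": 0,
    "k_folds": 5,
    "thresholds": {"gwas_p": 1e-4, "epistasis_p": 1e-5, "min_breed_n": 200},
    "gwas_background": "pedigree",  # "pedigree" (tabular A) or "grm"
}


def _merged(config: dict) -> dict:
    cfg = {**DEFAULTS, **config}
    cfg["thresholds"] = {**DEFAULTS["thresholds"], **config.get("thresholds", {})}
    return cfg


def simulate_stage(cfg: dict, outdir: Path):
    sim = cfg.get("simulate", {})
    sc = SimConfig(
        n_breeds=sim.get("n_breeds", 2),
        animals_per_breed=sim.get("animals_per_breed", 400),
        n_sires_per_breed=sim.get("n_sires_per_breed", 20),
        n_snps=sim.get("n_snps", 800),
        maf_floor=sim.get("maf_floor", 0.05),
        seed=cfg["seed"],
    )
    G, ped = simulate_genotypes(sc)
    trait = sim.get("trait", {})
    n_epi = trait.get("n_epistatic_pairs", 2)
    truth = truth_from_fractions(
        G,
        va_frac=trait.get("va_frac", 0.4),
        vd_frac=trait.get("vd_frac", 0.1),
        n_causal=trait.get("n_causal"),
        dominance_direction=trait.get("dominance_direction", 0),
        polygenic_frac=trait.get("polygenic_frac", 0.0),
        seed=cfg["seed"] + 1,
        scale=trait.get("scale", "realized"),
    )
    # lead SNPs anchor the planted interactions, mirroring a lead-SNP design
    rng = np.random.default_rng(np.random.SeedSequence(cfg["seed"] + 2))
    leads = []
    if n_epi > 0:
        m_scale = trait.get("epistatic_effect", 0.0)
        chosen = rng.choice(G.n_snps, size=2 * n_epi, replace=False)
        pairs = [(int(chosen[2 * i]), int(chosen[2 * i + 1]), m_scale) for i in range(n_epi)]
        truth.causal_epistatic = pairs
        leads = [G.snps["snp"].iloc[j] for j, _, _ in pairs]
    y, components = simulate_phenotypes(G, ped, truth, seed=cfg["seed"] + 3)
    log.info("simulated %d animals x %d SNPs in %d breed(s)",
             G.n_animals, G.n_snps, sc.n_breeds)
    hio.write_plink(G, outdir / "genotypes", ped)
    ped.to_csv(outdir / "pedigree.tsv", sep="\t", index=False)
    breed = ped.set_index("animal").loc[G.animals, "breed"]
    pheno = pd.DataFrame({"animal": G.animals, "breed": breed.values, "y": y})
    hio.write_table(pheno, outdir / "phenotypes.tsv", cfg["seed"], cfg)
    truth_tab = pd.DataFrame(
        [("additive", i, e) for i, e in truth.causal_additive]
        + [("dominance", i, e) for i, e in truth.causal_dominance]
        + [(f"epistatic:{j}", i, e) for j, i, e in truth.causal_epistatic],
        columns=["kind", "snp_index", "effect"],
    )
    hio.write_table(truth_tab, outdir / "truth.tsv", cfg["seed"], cfg)
    hio.write_table(components.var(ddof=1).rename("variance").reset_index(),
                    outdir / "realized_components.tsv", cfg["seed"], cfg)
    (outdir / "lead_snps.txt").write_text("\n".join(leads) + ("\n" if leads else ""))
    return G, ped, pheno, leads


def load_stage(cfg: dict):
    paths = cfg["inputs"]
    gpath = Path(paths["genotypes"])
    if gpath.suffix in (".tsv", ".txt"):
        G = hio.read_dosage_tsv(gpath)
    else:
        G = hio.read_plink(gpath.with_suffix(""), b_allele=cfg.get("b_allele", "a1"))
    excl = cfg.get("exclude_chromosomes", ["X"])
    n_before = G.n_snps
    G = G.drop_chromosomes(tuple(str(c) for c in excl))
    if G.n_snps < n_before:
        log.info("dropped %d SNPs on excluded chromosomes %s", n_before - G.n_snps, excl)
    ped = hio.read_pedigree(paths["pedigree"]) if "pedigree" in paths else None
    pheno = hio.read_phenotypes(paths["phenotypes"])
    leads = hio.read_snp_list(paths["lead_snps"]) if "lead_snps" in paths else []
    return G, ped, pheno, leads


def run_pipeline(config: dict, output_dir: str | Path) -> dict:
    """Execute the full analysis; returns a dict of the headline results."""
    cfg = _merged(config)
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    results: dict = {}

    stage = "simulate/load"
    try:
        if "inputs" in cfg:
            G, ped, pheno, leads = load_stage(cfg)
        else:
            G, ped, pheno, leads = simulate_stage(cfg, outdir)
        trait_col = cfg.get("trait", "y")
        pheno = pheno[pheno["animal"].isin(G.animals)].set_index("animal").loc[G.animals]
        y = pheno[trait_col].to_numpy(dtype=float)

        stage = "kinship"
        Gmat, Dmat, freqs = genomic_matrices(G)
        het = heterozygosity(G, freqs)
        n_drop = int((~freqs.retained).sum())
        log.info("kinship: %d SNPs retained, %d dropped by the frequency floor",
                 int(freqs.retained.sum()), n_drop)
        hio.write_gcta_grm(Gmat, outdir / "grm", int(freqs.retained.sum()))
        hio.write_gcta_grm(Dmat, outdir / "drm", int(freqs.retained.sum()))
        results["n_snps_retained"] = int(freqs.retained.sum())

        stage = "varcomp"
        factors = {"breed": pheno["breed"].to_numpy()} if "breed" in pheno.columns else {}
        covs = {c: pheno[c].to_numpy(float) for c in cfg.get("fixed_covariates", [])}
        spec_am = build_spec(y, covariates=covs, factors=factors, het=het,
                             random_terms=[("additive", Gmat.values)])
        spec_adm = build_spec(y, covariates=covs, factors=factors, het=het,
                              random_terms=[("additive", Gmat.values),
                                            ("dominance", Dmat.values)])
        fit_am = reml_fit(spec_am)
        fit_adm = reml_fit(spec_adm)
        stat, pval = lrt_dominance(fit_am, fit_adm)
        rows = []
        for tag, fit in (("AM", fit_am), ("ADM", fit_adm)):
            vp = fit.vp
            rows.append({
                "model": tag, "V_P": vp,
                "V_A/V_P": fit.sigma2.get("additive", 0.0) / vp,
                "V_D/V_P": fit.sigma2.get("dominance", 0.0) / vp,
                "V_G/V_P": (fit.sigma2.get("additive", 0.0)
                            + fit.sigma2.get("dominance", 0.0)) / vp,
                "het_beta": fit.het_beta, "het_t": fit.het_t,
                "logL": fit.loglik,
            })
        varcomp = pd.DataFrame(rows)
        varcomp["lrt_dominance"] = [np.nan, stat]
        varcomp["lrt_p"] = [np.nan, pval]
        hio.write_table(varcomp, outdir / "varcomp.tsv", seed, cfg)
        results.update({
            "va_vp_adm": varcomp.loc[1, "V_A/V_P"], "vd_vp_adm": varcomp.loc[1, "V_D/V_P"],
            "het_t_adm": fit_adm.het_t, "lrt_dominance": stat, "lrt_p": pval,
        })

        stage = "gwas"
        Xf = spec_am.X[:, [i for i in range(spec_am.X.shape[1]) if i != spec_am.het_index]]
        if cfg["gwas_background"] == "pedigree" and ped is not None:
            K_bg = pedigree_A(ped, animals=list(G.animals)).values
        else:
            K_bg = Gmat.values
        bg = fit_null_background(y, Xf, K_bg)
        gwas_df, summary = scan(G, bg, threshold=cfg["thresholds"]["gwas_p"])
        hio.write_table(gwas_df, outdir / "gwas.tsv", seed, cfg)
        hio.write_table(pd.DataFrame([summary.__dict__]), outdir / "gwas_summary.tsv", seed, cfg)
        results.update({
            "gwas_n_significant": summary.n_significant, "gwas_n_tested": summary.n_tested,
            "gwas_fdr": summary.fdr, "gwas_n_positive": summary.n_positive,
            "gwas_n_negative": summary.n_negative,
        })

        stage = "epistasis"
        if leads:
            epi_df, counts = scan_all_leads(G, bg, leads,
                                            threshold=cfg["thresholds"]["epistasis_p"])
            hio.write_table(epi_df, outdir / "epistasis.tsv", seed, cfg)
            hio.write_table(counts.rename_axis("lead").reset_index(),
                            outdir / "epistasis_counts.tsv", seed, cfg)
            results["epistasis_n_significant"] = int(counts.sum())

        stage = "crossval"
        if ped is not None:
            folds = sire_family_folds(ped, k=cfg["k_folds"], seed=seed,
                                      animals=list(G.animals))
            hio.write_table(folds.folds.rename_axis("animal").reset_index(),
                            outdir / "folds.tsv", seed, cfg)
            # discovery = folds 2..k, validation = fold 1 (concordance check)
            val = folds.animals_in(1)
            disc = [a for a in G.animals if a not in set(val)]
            pos = {a: i for i, a in enumerate(G.animals)}
            di = np.array([pos[a] for a in disc])
            vi = np.array([pos[a] for a in val])
            bg_d = fit_null_background(y[di], Xf[di], K_bg[np.ix_(di, di)])
            G_d = G.subset_animals(disc)
            disc_df, _ = scan(G_d, bg_d, threshold=cfg["thresholds"]["gwas_p"])
            bg_v = fit_null_background(y[vi], Xf[vi], K_bg[np.ix_(vi, vi)])
            conc = sign_concordance(disc_df, G.subset_animals(val), bg_v,
                                    threshold=cfg["thresholds"]["gwas_p"])
            if conc is not None:
                hio.write_table(
                    pd.DataFrame([{k: v for k, v in conc.__dict__.items() if k != "by_sign"}]),
                    outdir / "concordance.tsv", seed, cfg)
                results.update({"concordance_pct": conc.percentage,
                                "concordance_chi2": conc.chi2, "concordance_p": conc.p_value})
            matrices = {"additive": Gmat, "dominance": Dmat}
            breeds = pheno["breed"] if "breed" in pheno.columns else pd.Series("all", index=pheno.index)
            acc_rows = []
            for model in ("AM", "ADM"):
                pred = cv_predict(matrices, y, Xf, folds, list(G.animals), model=model)
                acc = accuracy_by_breed(pred["g_hat"], pred["y_corrected"], breeds,
                                        min_n=cfg["thresholds"]["min_breed_n"], model=model)
                acc.per_breed["model"] = model
                acc_rows.append(acc)
                results[f"cv_accuracy_{model.lower()}"] = acc.overall
            hio.write_table(pd.concat([a.per_breed for a in acc_rows]),
                            outdir / "accuracy.tsv", seed, cfg)
    except Exception as err:
        log.error("pipeline failed in stage %s: %s", stage, err)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    hio.write_table(pd.DataFrame(sorted(results.items()), columns=["quantity", "value"]),
                    outdir / "results.tsv", seed, cfg)
    return results
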