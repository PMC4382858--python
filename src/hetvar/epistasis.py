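"""Additive-by-additive interaction scans anchored on lead SNPs.

For a lead SNP j and each partner SNP i the model fits the additive dosage
of the lead (l_j), the additive dosage of the partner (s_i) and their
elementwise product (l_j o s_i) simultaneously as covariates on top of the
fixed effects and the polygenic background, and Wald-tests the interaction
coefficient m_ji.  Only lead x genome scans are offered — an all-pairs scan
would swamp any multiple-testing budget, and the lead SNPs are user input
(established additive hits), not discovered here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MISSING, GenotypeMatrix
from .gwas import BackgroundFit, _joint_gls


@dataclass
class EpistasisRecord:
    lead: str
    partner: str
    u_lead: float        # additive effect of the lead SNP in this pair fit
    a_partner: float     # additive effect of the partner SNP
    m_interaction: float
    m_se: float
    p_interaction: float


def scan_lead(
    G: GenotypeMatrix,
    bg: BackgroundFit,
    lead_snp: str,
    threshold: float = 1e-5,
) -> tuple[pd.DataFrame, int]:
    """Interaction scan of one lead SNP against every other SNP.

    Returns per-partner records and the count of interactions significant at
    the threshold.  Partners whose interaction contrast is inestimable
    (perfect collinearity, e.g. the lead itself) are skipped.
    """
    ids = G.snps["snp"].tolist()
    if lead_snp not in ids:
        raise ValueError(f"lead SNP {lead_snp!r} not in the panel")
    j = ids.index(lead_snp)
    l = G.genotypes[:, j].astype(float)
    l[l == MISSING] = l[l != MISSING].mean()
    if np.ptp(l) == 0:
        raise ValueError(f"lead SNP {lead_snp!r} is monomorphic")
    rows = []
    for i in range(G.n_snps):
        if i == j:
            continue
        s = G.genotypes[:, i].astype(float)
        s[s == MISSING] = s[s != MISSING].mean()
        if np.ptp(s) == 0:
            continue
        covars = np.column_stack([l, s, l * s])
        if np.linalg.matrix_rank(covars - covars.mean(axis=0)) < 3:
            continue  # interaction contrast inestimable
        try:
            b, se, p, _ = _joint_gls(bg, covars)
        except np.linalg.LinAlgError:
            continue
        rows.append(EpistasisRecord(lead_snp, ids[i], b[0], b[1], b[2], se[2], p[2]))
    df = pd.DataFrame([r.__dict__ for r in rows])
    n_sig = int((df["p_interaction"] < threshold).sum()) if len(df) else 0
    return df, n_sig


def scan_all_leads(
    G: GenotypeMatrix,
    bg: BackgroundFit,
    lead_snps,
    threshold: float = 1e-5,
) -> tuple[pd.DataFrame, pd.Series]:
    """Run scan_lead for each lead SNP; returns stacked records and the
    per-lead significant-interaction counts."""
    parts, counts = [], {}
    for lead in lead_snps:
        df, n_sig = scan_lead(G, bg, lead, threshold)
        parts.append(df)
        counts[lead] = n_sig
    stacked = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
    return stacked, pd.Series(counts, name="n_significant")


def allele_effect_table(u_lead: float, a_partner: float, m_interaction: float) -> pd.DataFrame:
    """2x2 combined-effect table for a lead/partner pair.

    The (A, A) cell is the baseline 0; (A, B) carries the partner's B-allele
    effect; (B, A) the lead's; and (B, B) their sum plus the interaction.
    """
    for v in (u_lead, a_partner, m_interaction):
        if not np.isfinite(v):
            raise ValueError("allele-effect table needs finite estimates")
    return pd.DataFrame(
        [[0.0, a_partner], [u_lead, u_lead + a_partner + m_interaction]],
        index=pd.Index(["A", "B"], name="lead_allele"),
        columns=pd.Index(["A", "B"], name="partner_allele"),
    )


def poisson_null_count(threshold: float, n_tested: int) -> float:
    """Expected significant interactions under the global null: P * T."""
    return threshold * n_tested
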