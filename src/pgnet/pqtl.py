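"""Variant-protein association mapping and pQTL architecture summaries.

The scan regresses each protein's abundance on each variant's dosage
with the proximity-extension-assay covariate design (age, age^2, sex,
age*sex, age^2*sex, principal components).  Covariates are projected
out of dosages and abundances once, after which every (variant,
protein) slope, SE, and t-test follows in closed form — algebraically
identical to per-pair OLS on the full design.

p-values are carried as -log10(p) throughout so that associations far
below the double-precision underflow limit remain representable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import MISSING

logger = logging.getLogger(__name__)

LOG10 = np.log(10.0)
NLP_CAP = 5000.0  # -log10(p) saturation for exact fits (t -> inf)


def pqtl_covariate_design(covariates: pd.DataFrame) -> np.ndarray:
    """Design matrix: intercept, age, age^2, sex, age*sex, age^2*sex, PCs."""
    age = covariates["age"].to_numpy(dtype=float)
    sex = covariates["sex"].to_numpy(dtype=float)
    age_c = age - age.mean()
    cols = [
        np.ones(len(age)),
        age_c,
        age_c**2,
        sex,
        age_c * sex,
        age_c**2 * sex,
    ]
    for c in covariates.columns:
        if c.startswith("pc"):
            cols.append(covariates[c].to_numpy(dtype=float))
    return np.column_stack(cols)


def _neg_log10_p_from_t(t: np.ndarray, df: int) -> np.ndarray:
    """Two-sided t-test -log10(p), computed in log space (underflow-safe)."""
    logp = np.log(2.0) + stats.t.logsf(np.abs(t), df)
    nlp = -logp / LOG10
    return np.where(np.isfinite(nlp), np.minimum(nlp, NLP_CAP), NLP_CAP)


def pqtl_scan(
    proteins: pd.DataFrame,
    genotypes: np.ndarray,
    covariates: pd.DataFrame,
    variant_table: pd.DataFrame,
    alpha: float = 5e-8,
) -> pd.DataFrame:
    """All-pairs pQTL scan; emits records with p < alpha.

    Missing dosages are mean-imputed for the vectorized scan.  Constant
    dosage or abundance columns are skipped with a log message.
    Returns columns: variant_id, protein, beta, se, neg_log10_p.
    """
    if len(proteins) != genotypes.shape[0] or len(covariates) != genotypes.shape[0]:
        raise ValueError("sample dimension mismatch across matrices")
    C = pqtl_covariate_design(covariates)
    n, p_cov = C.shape
    df = n - p_cov - 1
    Q, _ = np.linalg.qr(C)

    X = genotypes.astype(float)
    X[X == MISSING] = np.nan
    colmean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), colmean, X)
    Y = proteins.to_numpy(dtype=float)

    Xr = X - Q @ (Q.T @ X)
    Yr = Y - Q @ (Q.T @ Y)
    Sx = (Xr**2).sum(axis=0)
    Sy = (Yr**2).sum(axis=0)

    const_x = Sx < 1e-10
    if const_x.any():
        logger.info("pqtl_scan: skipping %d constant dosage columns", const_x.sum())
    const_y = Sy < 1e-10
    if const_y.any():
        logger.info("pqtl_scan: skipping %d constant protein columns", const_y.sum())

    Sx_safe = np.where(const_x, 1.0, Sx)
    XtY = Xr.T @ Yr  # variants x proteins
    beta = XtY / Sx_safe[:, None]
    rss = np.maximum(Sy[None, :] - XtY**2 / Sx_safe[:, None], 0.0)
    sigma2 = rss / df
    # exact-fit guard (protein identical to dosage): SE floor keeps t finite
    se = np.sqrt(np.maximum(sigma2, 1e-300) / Sx_safe[:, None])
    t = beta / se
    nlp = _neg_log10_p_from_t(t, df)
    nlp[const_x, :] = 0.0
    nlp[:, const_y] = 0.0

    threshold = -np.log10(alpha)
    vi, pi = np.nonzero(nlp > threshold)
    out = pd.DataFrame(
        {
            "variant_id": variant_table["variant_id"].to_numpy()[vi],
            "protein": proteins.columns.to_numpy()[pi],
            "beta": beta[vi, pi],
            "se": se[vi, pi],
            "neg_log10_p": nlp[vi, pi],
        }
    )
    return out.sort_values(["variant_id", "protein"]).reset_index(drop=True)


def classify_cis_trans(
    records: pd.DataFrame,
    variant_table: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    protein_genes: dict[str, str] | None = None,
    window_bp: int = 1000,
) -> pd.DataFrame:
    """Label each record cis/trans/unknown relative to the coding gene.

    cis iff the variant lies on the gene's chromosome with 1-based
    position inside [gene_start - window, gene_end + window], both ends
    inclusive (gene intervals converted from 0-based half-open).
    Unannotated proteins get "unknown".
    """
    if protein_genes is None:
        protein_genes = {g: g for g in gene_annotation["gene"]}
    ann = gene_annotation.set_index("gene")
    vt = variant_table.set_index("variant_id")
    labels = []
    for _, row in records.iterrows():
        gene = protein_genes.get(row["protein"])
        if gene is None or gene not in ann.index:
            labels.append("unknown")
            continue
        g = ann.loc[gene]
        v = vt.loc[row["variant_id"]]
        start_1based = int(g["start"]) + 1
        end_1based = int(g["end"])
        same_chrom = str(v["chrom"]) == str(g["chrom"])
        in_window = (
            start_1based - window_bp <= int(v["pos"]) <= end_1based + window_bp
        )
        labels.append("cis" if same_chrom and in_window else "trans")
    out = records.copy()
    out["cis_flag"] = labels
    return out


def intersect_gwas_pqtl(
    gwas_hits: pd.DataFrame | set[str], pqtl_records: pd.DataFrame
) -> tuple[pd.DataFrame, set[str]]:
    """GWAS-significant variants joined to significant pQTL records.

    Returns all (variant, protein) association pairs whose variant is a
    GWAS hit, plus the distinct protein set.
    """
    if isinstance(gwas_hits, pd.DataFrame):
        hit_ids = set(gwas_hits["variant_id"])
    else:
        hit_ids = set(gwas_hits)
    pairs = pqtl_records[pqtl_records["variant_id"].isin(hit_ids)].copy()
    return pairs.reset_index(drop=True), set(pairs["protein"])


@dataclass
class ArchitectureSummary:
    """Counts describing the pQTL architecture (cf. proteins-per-pQTL etc.)."""

    proteins_per_pqtl: dict[str, int] = field(default_factory=dict)
    pqtls_per_protein: dict[str, int] = field(default_factory=dict)
    n_cis_only_proteins: int = 0
    n_trans_only_proteins: int = 0
    n_both_proteins: int = 0
    n_unknown_proteins: int = 0
    n_trans_only_pqtls: int = 0

    @property
    def n_proteins(self) -> int:
        return (
            self.n_cis_only_proteins
            + self.n_trans_only_proteins
            + self.n_both_proteins
            + self.n_unknown_proteins
        )


def architecture_summary(records: pd.DataFrame) -> ArchitectureSummary:
    """Histograms of proteins-per-pQTL / pQTLs-per-protein and cis/trans mix."""
    if "cis_flag" not in records.columns:
        raise ValueError("records must be classified first (cis_flag column)")
    per_v = records.groupby("variant_id")["protein"].nunique().to_dict()
    per_p = records.groupby("protein")["variant_id"].nunique().to_dict()
    cis_only = trans_only = both = unknown = 0
    for _, sub in records.groupby("protein"):
        flags = set(sub["cis_flag"])
        if flags <= {"unknown"}:
            unknown += 1
        elif "cis" in flags and "trans" in flags:
            both += 1
        elif "cis" in flags:
            cis_only += 1
        else:
            trans_only += 1
    trans_only_v = sum(
        1
        for _, sub in records.groupby("variant_id")
        if set(sub["cis_flag"]) == {"trans"}
    )
    summary = ArchitectureSummary(
        proteins_per_pqtl=per_v,
        pqtls_per_protein=per_p,
        n_cis_only_proteins=cis_only,
        n_trans_only_proteins=trans_only,
        n_both_proteins=both,
        n_unknown_proteins=unknown,
        n_trans_only_pqtls=trans_only_v,
    )
    # conservation: histogram masses match record-derived counts
    assert len(summary.proteins_per_pqtl) == records["variant_id"].nunique()
    assert summary.n_proteins == records["protein"].nunique()
    return summary


def neg_log10_to_p(neg_log10_p: np.ndarray | float) -> np.ndarray | float:
    """Convert back to a linear p (floored at the double-precision limit)."""
    return np.power(10.0, -np.minimum(neg_log10_p, 300.0))
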