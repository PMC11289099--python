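"""Per-variant QC, case/control association, and fixed-effects meta-analysis.

The association test is a plain covariate-adjusted logistic regression
(maximum likelihood, or Firth-penalized on request) of case status on
allele dosage.  Meta-analysis is the classical fixed-effects scheme:
studies are combined with inverse-squared-SE weights after allele
harmonization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .synthetic import MISSING

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default QC thresholds (retained iff strictly above each threshold)
DEFAULT_QC = {"maf_min": 0.001, "call_rate_min": 0.95, "hwe_min": 1e-6, "info_min": 0.8}


class ConvergenceError(RuntimeError):
    """Logistic fit failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


class SeparationError(RuntimeError):
    """Perfect separation without the Firth penalty."""


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg equilibrium test.

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote counts no more probable than the observed one.
    Monomorphic samples return p = 1.
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 or int(c) != c for c in counts):
        raise ValueError("genotype counts must be nonnegative integers")
    n = sum(counts)
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_AA, n_Aa, n_aa = (int(c) for c in counts)
    rare = 2 * min(n_AA, n_aa) + n_Aa  # rare-allele count
    if rare == 0:
        return 1.0

    # het counts share the parity of the rare-allele count
    het_values = list(range(rare % 2, min(rare, 2 * n - rare) + 1, 2))
    # unnormalized probabilities by the standard recurrence, anchored mid-range
    probs = {}
    mid = het_values[len(het_values) // 2]
    probs[mid] = 1.0
    # going down: P(h-2)/P(h) = h*(h-1) / ((rare-h+2)/2 * (2n-rare-h+2)/2)... use
    # ratio P(h)/P(h+2) derived from the conditional distribution
    for h in range(mid, het_values[0], -2):
        hom_r = (rare - h) // 2
        hom_c = (2 * n - rare - h) // 2
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
    for h in range(mid, het_values[-1], 2):
        hom_r = (rare - h) // 2
        hom_c = (2 * n - rare - h) // 2
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2) * (h + 1))
    total = sum(probs.values())
    p_obs = probs[n_Aa]
    p = sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p)


# ---------------------------------------------------------------------------
# variant QC


def variant_qc(
    genotypes: np.ndarray,
    info: np.ndarray | None = None,
    maf_min: float = DEFAULT_QC["maf_min"],
    call_rate_min: float = DEFAULT_QC["call_rate_min"],
    hwe_min: float = DEFAULT_QC["hwe_min"],
    info_min: float = DEFAULT_QC["info_min"],
) -> tuple[np.ndarray, pd.DataFrame]:
    """Filter variants on MAF, call rate, HWE, and (optionally) INFO.

    A variant is retained iff it strictly passes every filter.  Returns
    the boolean retain mask and a per-variant QC report; a variant
    failing several filters is counted under each.
    """
    n, m = genotypes.shape
    called = genotypes != MISSING
    call_rate = called.mean(axis=0)
    maf = np.zeros(m)
    hwe_p = np.ones(m)
    for j in range(m):
        g = genotypes[called[:, j], j]
        if g.size == 0:
            continue
        f = g.mean() / 2.0
        maf[j] = min(f, 1.0 - f)
        n_aa = int((g == 0).sum())
        n_het = int((g == 1).sum())
        n_AA = int((g == 2).sum())
        hwe_p[j] = hwe_test(n_AA, n_het, n_aa)

    fail_maf = maf <= maf_min
    fail_cr = call_rate <= call_rate_min
    fail_hwe = hwe_p <= hwe_min
    if info is not None:
        fail_info = np.asarray(info) <= info_min
    else:
        fail_info = np.zeros(m, dtype=bool)
    retain = ~(fail_maf | fail_cr | fail_hwe | fail_info)
    report = pd.DataFrame(
        {
            "maf": maf,
            "call_rate": call_rate,
            "hwe_p": hwe_p,
            "info": np.asarray(info) if info is not None else np.nan,
            "fail_maf": fail_maf,
            "fail_call_rate": fail_cr,
            "fail_hwe": fail_hwe,
            "fail_info": fail_info,
            "retained": retain,
        }
    )
    if not retain.any():
        warnings.warn("variant QC removed every variant", stacklevel=2)
    return retain, report


# ---------------------------------------------------------------------------
# logistic association


@dataclass
class AssocResult:
    beta: float
    se: float
    p: float
    n: int
    n_cases: int
    converged: bool
    firth: bool


def _firth_logistic(
    X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Firth-penalized logistic regression (Jeffreys-prior score correction)."""
    n, k = X.shape
    beta = np.zeros(k)
    trace: list[float] = []
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        XW = X * w[:, None]
        info_mat = X.T @ XW
        try:
            info_inv = np.linalg.inv(info_mat)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix", trace) from exc
        # hat-matrix diagonal of the weighted design
        h = np.einsum("ij,jk,ik->i", XW, info_inv, X)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        beta = beta + step
        delta = float(np.max(np.abs(step)))
        trace.append(delta)
        if delta < tol:
            se = np.sqrt(np.diag(info_inv))
            return beta, se, trace
    raise ConvergenceError(f"Firth logistic did not converge in {max_iter}", trace)


def logistic_assoc(
    phenotype: np.ndarray,
    dosage: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    firth: bool = False,
    mean_impute: bool = False,
) -> AssocResult:
    """Logistic regression of case status on dosage plus covariates.

    Missing dosages (sentinel or NaN) are dropped listwise by default,
    or mean-imputed with ``mean_impute=True``.  With ``firth=True`` the
    Jeffreys-prior penalized fit is used, which stays finite under
    separation.
    """
    y = np.asarray(phenotype, dtype=float)
    x = np.asarray(dosage, dtype=float).copy()
    x[x == MISSING] = np.nan
    if covariates is None:
        C = np.empty((len(y), 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    miss = np.isnan(x)
    if miss.any():
        if mean_impute:
            x[miss] = np.nanmean(x)
        else:
            keep = ~miss
            y, x, C = y[keep], x[keep], C[keep]
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 cases and 2 controls")

    X = np.column_stack([np.ones(len(y)), x, C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (collinear dosage/covariates)")

    if firth:
        beta, se, _ = _firth_logistic(X, y)
        b, s = beta[1], se[1]
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(y, X)
            try:
                fit = model.fit(disp=0, maxiter=100)
            except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
                raise SeparationError(str(exc)) from exc
        if not fit.mle_retvals.get("converged", False):
            # statsmodels hits maxiter under (quasi-)separation
            raise SeparationError("logistic fit did not converge (separation?)")
        if np.abs(fit.params[1]) > 15 or not np.isfinite(fit.bse[1]):
            raise SeparationError("implausible estimate; data may be separated")
        b, s = float(fit.params[1]), float(fit.bse[1])
    z = b / s
    p = 2.0 * norm.sf(abs(z))
    return AssocResult(
        beta=float(b),
        se=float(s),
        p=float(max(p, 5e-324)),
        n=len(y),
        n_cases=int(y.sum()),
        converged=True,
        firth=firth,
    )


def gwas_scan(
    genotypes: np.ndarray,
    variant_table: pd.DataFrame,
    phenotype: np.ndarray,
    covariates: pd.DataFrame,
    covariate_columns: list[str] | None = None,
    firth_fallback: bool = True,
    qc: bool = True,
    **qc_thresholds,
) -> pd.DataFrame:
    """Genome-wide per-variant logistic scan; returns a sumstats table.

    Covariates default to sex, year of birth, and the principal
    components present in the covariate table.  Variants failing QC are
    excluded up front; separated fits fall back to the Firth penalty.
    """
    if covariate_columns is None:
        covariate_columns = ["sex", "yob"] + [
            c for c in covariates.columns if c.startswith("pc")
        ]
    C = covariates[covariate_columns]
    if qc:
        retain, _ = variant_qc(genotypes, **qc_thresholds)
    else:
        retain = np.ones(genotypes.shape[1], dtype=bool)
    rows = []
    for j in np.flatnonzero(retain):
        x = genotypes[:, j]
        try:
            res = logistic_assoc(phenotype, x, C)
        except SeparationError:
            if not firth_fallback:
                continue
            res = logistic_assoc(phenotype, x, C, firth=True)
        except (ValueError, ConvergenceError):
            continue
        valid = x != MISSING
        eaf = float(genotypes[valid, j].mean() / 2.0)
        v = variant_table.iloc[j]
        rows.append(
            {
                "variant_id": v["variant_id"],
                "chrom": v["chrom"],
                "pos": int(v["pos"]),
                "effect_allele": v["effect_allele"],
                "other_allele": v["other_allele"],
                "eaf": eaf,
                "beta": res.beta,
                "se": res.se,
                "p": res.p,
                "n": res.n,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# meta-analysis


def _harmonize_pair(row) -> float | None:
    """Sign multiplier to align study-b alleles to study a, or None to drop."""
    ea_a, oa_a = row["effect_allele_a"], row["other_allele_a"]
    ea_b, oa_b = row["effect_allele_b"], row["other_allele_b"]
    ambiguous_a = COMPLEMENT.get(ea_a) == oa_a  # A/T or C/G pair
    if (ea_a, oa_a) == (ea_b, oa_b):
        flip = 1.0
    elif (ea_a, oa_a) == (oa_b, ea_b):
        flip = -1.0
    else:
        # try strand flip
        ea_bc, oa_bc = COMPLEMENT.get(ea_b), COMPLEMENT.get(oa_b)
        if (ea_a, oa_a) == (ea_bc, oa_bc):
            flip = 1.0
        elif (ea_a, oa_a) == (oa_bc, ea_bc):
            flip = -1.0
        else:
            return None
    if ambiguous_a:
        # strand-ambiguous: orientation only resolvable through frequency
        eaf_a, eaf_b = row["eaf_a"], row["eaf_b"]
        if abs(eaf_a - 0.5) < 0.08 or abs(eaf_b - 0.5) < 0.08:
            return None
        fb = eaf_b if flip > 0 else 1.0 - eaf_b
        same_side = (eaf_a - 0.5) * (fb - 0.5) > 0
        flip = flip if same_side else -flip
    return flip


def meta_fixed(records_a: pd.DataFrame, records_b: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effects inverse-variance meta-analysis of two studies.

    Only variants present in both studies are emitted.  Study-b effects
    are harmonized to study-a alleles (sign flip on swapped alleles;
    strand-ambiguous variants with uninformative frequencies dropped).
    """
    merged = records_a.merge(
        records_b, on="variant_id", suffixes=("_a", "_b"), how="inner"
    )
    rows = []
    for _, row in merged.iterrows():
        flip = _harmonize_pair(row)
        if flip is None:
            logger.info("meta: dropping %s (unharmonizable alleles)", row["variant_id"])
            continue
        b = np.array([row["beta_a"], flip * row["beta_b"]])
        se = np.array([row["se_a"], row["se_b"]])
        w = 1.0 / se**2
        beta_meta = float(np.sum(w * b) / np.sum(w))
        se_meta = float(1.0 / np.sqrt(np.sum(w)))
        z = beta_meta / se_meta
        rows.append(
            {
                "variant_id": row["variant_id"],
                "chrom": row["chrom_a"],
                "pos": row["pos_a"],
                "effect_allele": row["effect_allele_a"],
                "other_allele": row["other_allele_a"],
                "eaf": float(row["eaf_a"]),
                "beta_meta": beta_meta,
                "se_meta": se_meta,
                "z_meta": float(z),
                "p_meta": float(max(2.0 * norm.sf(abs(z)), 5e-324)),
                "n_studies": 2,
                "direction": "".join("+" if x >= 0 else "-" for x in b),
                "n": int(row["n_a"] + row["n_b"]),
            }
        )
    return pd.DataFrame(rows)


def genomewide_significant(records: pd.DataFrame, alpha: float = 5e-8) -> pd.DataFrame:
    """Strict subset with p < alpha (p-value column autodetected)."""
    pcol = "p_meta" if "p_meta" in records.columns else "p"
    if records.empty:
        return records.copy()
    return records[records[pcol] < alpha].copy()
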