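"""Two-sample Mendelian randomization, colocalization, and fine-mapping.

Instruments are cis-pQTL variants; the exposure is protein abundance
and the outcome a disease GWAS.  Estimators: Wald ratio (single
instrument), fixed-effect inverse-variance weighting, and the weighted
median (consistent when instruments carrying >= 50% of the weight are
valid).  Horizontal pleiotropy is screened with a simulation-based
global heterogeneity test.  Regional colocalization uses Wakefield
approximate Bayes factors with the H0-H4 hypothesis decomposition, and
fine-mapping uses the single-causal-variant ABF posterior.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .assoc import COMPLEMENT

logger = logging.getLogger(__name__)

#: Wakefield prior effect SD: case-control (log-odds) and quantitative traits
W_CC = 0.15**2
W_QT = 0.2**2

DEFAULT_PRIORS = {"p1": 1e-4, "p2": 1e-4, "p12": 1e-5}


# ---------------------------------------------------------------------------
# instrument selection and harmonization


def ld_clump(
    records: pd.DataFrame, R: pd.DataFrame, r2_max: float = 0.001
) -> pd.DataFrame:
    """Greedy LD clumping: accept by ascending p, reject r^2 >= r2_max.

    ``R`` is a correlation matrix indexed by variant id; variants absent
    from R are dropped with a log message.
    """
    known = records["variant_id"].isin(R.index)
    if (~known).any():
        logger.info("ld_clump: dropping %d variants absent from R", (~known).sum())
    recs = records[known].sort_values(
        ["p", "variant_id"], kind="mergesort"
    )  # stable: ties by id
    accepted: list[str] = []
    for vid in recs["variant_id"]:
        r2 = R.loc[vid, accepted].to_numpy(dtype=float) ** 2 if accepted else []
        if len(accepted) == 0 or np.all(np.asarray(r2) < r2_max):
            accepted.append(vid)
    return records[records["variant_id"].isin(accepted)].copy()


def harmonize(
    exposure: pd.DataFrame, outcome: pd.DataFrame, eaf_tol: float = 0.08
) -> pd.DataFrame:
    """Align outcome effects to the exposure effect allele.

    Swapped alleles flip the outcome beta; strand flips are resolved by
    complementing; palindromic (A/T, C/G) variants with effect-allele
    frequency within ``eaf_tol`` of 0.5 on either side are dropped as
    ambiguous, as are irreconcilable allele pairs.
    """
    merged = exposure.merge(
        outcome, on="variant_id", suffixes=("_exp", "_out"), how="inner"
    )
    rows = []
    for _, row in merged.iterrows():
        ea_e, oa_e = row["effect_allele_exp"], row["other_allele_exp"]
        ea_o, oa_o = row["effect_allele_out"], row["other_allele_out"]
        palindromic = COMPLEMENT.get(ea_e) == oa_e
        if palindromic and (
            abs(row["eaf_exp"] - 0.5) < eaf_tol or abs(row["eaf_out"] - 0.5) < eaf_tol
        ):
            logger.info("harmonize: dropping palindromic %s", row["variant_id"])
            continue
        if (ea_e, oa_e) == (ea_o, oa_o):
            flip = 1.0
        elif (ea_e, oa_e) == (oa_o, ea_o):
            flip = -1.0
        elif (ea_e, oa_e) == (COMPLEMENT.get(ea_o), COMPLEMENT.get(oa_o)):
            flip = 1.0
        elif (ea_e, oa_e) == (COMPLEMENT.get(oa_o), COMPLEMENT.get(ea_o)):
            flip = -1.0
        else:
            logger.info("harmonize: dropping irreconcilable %s", row["variant_id"])
            continue
        rows.append(
            {
                "variant_id": row["variant_id"],
                "beta_exposure": row["beta_exp"],
                "se_exposure": row["se_exp"],
                "beta_outcome": flip * row["beta_out"],
                "se_outcome": row["se_out"],
                "eaf_exposure": row["eaf_exp"],
                "eaf_outcome": row["eaf_out"] if flip > 0 else 1 - row["eaf_out"],
                "effect_allele": ea_e,
                "other_allele": oa_e,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "variant_id",
            "beta_exposure",
            "se_exposure",
            "beta_outcome",
            "se_outcome",
            "eaf_exposure",
            "eaf_outcome",
            "effect_allele",
            "other_allele",
        ],
    )


# ---------------------------------------------------------------------------
# MR estimators


@dataclass
class MRResult:
    protein: str
    method: str
    n_snp: int
    beta: float
    se: float
    p: float
    fdr: float | None = None


def _two_sided_p(beta: float, se: float) -> float:
    if beta == 0.0:
        return 1.0
    return float(max(2.0 * stats.norm.sf(abs(beta / se)), 5e-324))


def mr_wald(instruments: pd.DataFrame, protein: str = "") -> MRResult:
    """Single-instrument Wald ratio with first-order delta SE."""
    if len(instruments) != 1:
        raise ValueError("Wald ratio requires exactly one instrument")
    row = instruments.iloc[0]
    be, bo, so = row["beta_exposure"], row["beta_outcome"], row["se_outcome"]
    if be == 0:
        raise ZeroDivisionError("exposure effect is zero")
    beta = bo / be
    se = so / abs(be)
    return MRResult(protein, "Wald ratio", 1, float(beta), float(se), _two_sided_p(beta, se))


def mr_ivw(instruments: pd.DataFrame, protein: str = "") -> MRResult:
    """Fixed-effect IVW: weighted through-origin regression of outcome on exposure."""
    if len(instruments) < 2:
        return mr_wald(instruments, protein)
    be = instruments["beta_exposure"].to_numpy(dtype=float)
    bo = instruments["beta_outcome"].to_numpy(dtype=float)
    so = instruments["se_outcome"].to_numpy(dtype=float)
    denom = np.sum(be**2 / so**2)
    beta = float(np.sum(be * bo / so**2) / denom)
    se = float(1.0 / math.sqrt(denom))
    return MRResult(
        protein, "Inverse variance weighted", len(instruments), beta, se,
        _two_sided_p(beta, se),
    )


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with linear interpolation between bracketing values."""
    order = np.argsort(values)
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    cum = (np.cumsum(w) - 0.5 * w) / w.sum()
    if cum[0] >= 0.5:
        return float(v[0])
    if cum[-1] <= 0.5:
        return float(v[-1])
    below = int(np.searchsorted(cum, 0.5, side="right") - 1)
    lo, hi = cum[below], cum[below + 1]
    frac = (0.5 - lo) / (hi - lo)
    return float(v[below] + frac * (v[below + 1] - v[below]))


def mr_weighted_median(
    instruments: pd.DataFrame,
    protein: str = "",
    n_boot: int = 1000,
    seed: int = 0,
) -> MRResult:
    """Weighted-median MR with parametric-bootstrap SE."""
    if len(instruments) < 3:
        raise ValueError("weighted median requires >= 3 instruments")
    be = instruments["beta_exposure"].to_numpy(dtype=float)
    bo = instruments["beta_outcome"].to_numpy(dtype=float)
    se_e = instruments["se_exposure"].to_numpy(dtype=float)
    so = instruments["se_outcome"].to_numpy(dtype=float)
    ratios = bo / be
    weights = be**2 / so**2
    est = weighted_median(ratios, weights)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        be_b = rng.normal(be, se_e)
        bo_b = rng.normal(bo, so)
        ok = be_b != 0
        boots[b] = weighted_median(bo_b[ok] / be_b[ok], be_b[ok] ** 2 / so[ok] ** 2)
    se = float(boots.std(ddof=1))
    return MRResult(
        protein, "Weighted median", len(instruments), float(est), se,
        _two_sided_p(est, se),
    )


def pleiotropy_global_test(
    instruments: pd.DataFrame, n_sim: int = 1000, seed: int = 0
) -> float | None:
    """Global horizontal-pleiotropy test (simulation-based heterogeneity).

    Observed statistic: weighted residual sum of squares of the outcome
    effects about leave-one-out IVW fits.  The null distribution comes
    from parametric simulation under no pleiotropy; p uses the +1
    convention.  Returns None when fewer than 4 instruments.
    """
    m = len(instruments)
    if m < 4:
        return None
    be = instruments["beta_exposure"].to_numpy(dtype=float)
    bo = instruments["beta_outcome"].to_numpy(dtype=float)
    se_e = instruments["se_exposure"].to_numpy(dtype=float)
    so = instruments["se_outcome"].to_numpy(dtype=float)

    def loo_rss(bo_x: np.ndarray, be_x: np.ndarray) -> float:
        w = be_x**2 / so**2
        num = be_x * bo_x / so**2
        tot_num, tot_w = num.sum(), w.sum()
        beta_loo = (tot_num - num) / (tot_w - w)
        return float(np.sum((bo_x - be_x * beta_loo) ** 2 / so**2))

    rss_obs = loo_rss(bo, be)
    w_all = be**2 / so**2
    beta_ivw = float(np.sum(be * bo / so**2) / w_all.sum())
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_sim):
        be_s = rng.normal(be, se_e)
        bo_s = rng.normal(be * beta_ivw, so)
        if loo_rss(bo_s, be_s) >= rss_obs:
            exceed += 1
    return (1 + exceed) / (n_sim + 1)


# ---------------------------------------------------------------------------
# colocalization and fine-mapping


@dataclass
class ColocResult:
    region: str
    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float
    n_snps: int
    priors: dict

    def as_dict(self) -> dict:
        return {
            "region": self.region,
            "PP.H0": self.pp_h0,
            "PP.H1": self.pp_h1,
            "PP.H2": self.pp_h2,
            "PP.H3": self.pp_h3,
            "PP.H4": self.pp_h4,
            "n_snps": self.n_snps,
        }


def wakefield_labf(
    beta: np.ndarray, se: np.ndarray, w: float = W_CC
) -> np.ndarray:
    """Log approximate Bayes factor for one association.

    lABF = 0.5 * [ln(V / (V + W)) + z^2 * W / (V + W)] with V = se^2
    and W the prior effect variance.
    """
    V = np.asarray(se, dtype=float) ** 2
    z2 = (np.asarray(beta, dtype=float) / se) ** 2
    return 0.5 * (np.log(V / (V + w)) + z2 * w / (V + w))


def _logdiffexp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b; -inf when the difference vanishes."""
    if b >= a:
        return -np.inf
    return a + math.log1p(-math.exp(b - a))


def coloc_abf(
    trait1: pd.DataFrame,
    trait2: pd.DataFrame,
    priors: dict | None = None,
    w1: float = W_QT,
    w2: float = W_CC,
    region: str = "",
) -> ColocResult:
    """Approximate-Bayes-factor colocalization over a shared region.

    H0 no association; H1/H2 one trait only; H3 two distinct causal
    variants; H4 one shared causal variant.  Sums are accumulated with
    log-sum-exp throughout.
    """
    pri = dict(DEFAULT_PRIORS)
    if priors:
        pri.update(priors)
    merged = trait1.merge(trait2, on="variant_id", suffixes=("_1", "_2"), how="inner")
    m = len(merged)
    if m == 0:
        raise ValueError("no shared variants in the region")
    if m < 2:
        logger.warning("coloc_abf: only %d shared variant(s) in region", m)
    l1 = wakefield_labf(merged["beta_1"].to_numpy(), merged["se_1"].to_numpy(), w1)
    l2 = wakefield_labf(merged["beta_2"].to_numpy(), merged["se_2"].to_numpy(), w2)
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    lH0 = 0.0
    lH1 = math.log(pri["p1"]) + s1
    lH2 = math.log(pri["p2"]) + s2
    lH3 = math.log(pri["p1"]) + math.log(pri["p2"]) + _logdiffexp(s1 + s2, s12)
    lH4 = math.log(pri["p12"]) + s12
    ls = np.array([lH0, lH1, lH2, lH3, lH4])
    pp = np.exp(ls - logsumexp(ls))
    return ColocResult(region, *(float(x) for x in pp), n_snps=m, priors=pri)


@dataclass
class CredibleSet:
    region: str
    pips: pd.DataFrame  # variant_id, pip, in_cs95 — sorted by descending PIP
    members: list[str]
    mass: float


def finemap_single_causal(
    records: pd.DataFrame, w: float = W_CC, region: str = "", level: float = 0.95
) -> CredibleSet:
    """Single-causal-variant fine-mapping via ABF posteriors.

    PIP_j = ABF_j / sum(ABF); the credible set is the minimal
    descending-PIP prefix whose cumulative mass reaches ``level``.
    Input order does not affect the posteriors.
    """
    if records.empty:
        raise ValueError("empty region")
    labf = wakefield_labf(records["beta"].to_numpy(), records["se"].to_numpy(), w)
    pip = np.exp(labf - logsumexp(labf))
    df = pd.DataFrame({"variant_id": records["variant_id"].to_numpy(), "pip": pip})
    df = df.sort_values(
        ["pip", "variant_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    cum = df["pip"].cumsum()
    n_members = int(np.searchsorted(cum.to_numpy(), level - 1e-12) + 1)
    n_members = min(n_members, len(df))
    df["in_cs95"] = np.arange(len(df)) < n_members
    members = list(df["variant_id"].iloc[:n_members])
    return CredibleSet(region, df, members, float(cum.iloc[n_members - 1]))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# per-protein MR routing


def mr_per_protein(
    instruments_by_protein: dict[str, pd.DataFrame],
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Route each protein to the applicable estimator and apply BH FDR.

    1 instrument -> Wald ratio; >= 2 -> IVW (primary); >= 3 additionally
    reports the weighted median.  FDR is computed across the primary
    estimates, matching one row per protein.
    """
    primary: list[MRResult] = []
    extra: list[MRResult] = []
    for i, (protein, inst) in enumerate(sorted(instruments_by_protein.items())):
        if inst.empty:
            continue
        if len(inst) == 1:
            primary.append(mr_wald(inst, protein))
        else:
            primary.append(mr_ivw(inst, protein))
            if len(inst) >= 3:
                extra.append(
                    mr_weighted_median(inst, protein, n_boot=n_boot, seed=seed + i)
                )
    if primary:
        q = bh_fdr([r.p for r in primary])
        for r, qv in zip(primary, q):
            r.fdr = float(qv)
    rows = [
        {
            "protein": r.protein,
            "method": r.method,
            "n_snp": r.n_snp,
            "beta": r.beta,
            "se": r.se,
            "p": r.p,
            "fdr": r.fdr,
        }
        for r in primary + extra
    ]
    return pd.DataFrame(
        rows, columns=["protein", "method", "n_snp", "beta", "se", "p", "fdr"]
    )
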