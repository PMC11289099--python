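"""Pathway enrichment, evidence triangulation, genotype-stratified
abundance tests, and variant-to-chromatin-loop mapping.

Enrichment is a hypergeometric over-representation test against a
panel background (the assayed-protein universe, never the whole
genome, unless explicitly requested), with BH FDR across the tested
sets.  Triangulation flags proteins supported by the three target
sets: (a) pQTL-associated, (b) top-module members that are also
pQTL-associated, (c) first-degree GWAS-neighbors that are also
pQTL-associated.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from . import netmod
from .causal import bh_fdr

logger = logging.getLogger(__name__)


def _norm_symbol(g: str) -> str:
    return str(g).strip().upper()


def pathway_enrichment(
    query_genes,
    collection: dict[str, set[str]],
    background,
    fdr_max: float = 0.05,
    min_overlap: int = 3,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in the query.

    Query genes outside the background are logged and intersected away.
    Sets overlapping the query below ``min_overlap`` are skipped.
    Returns all tested sets with p, BH FDR, enrichment ratio, and a
    significance flag at ``fdr_max``.
    """
    bg = {_norm_symbol(g) for g in background}
    if not bg:
        raise ValueError("empty background")
    query = {_norm_symbol(g) for g in query_genes}
    outside = query - bg
    if outside:
        logger.info("pathway_enrichment: %d query genes outside background", len(outside))
        query &= bg
    N, q = len(bg), len(query)
    rows = []
    for name in sorted(collection):
        members = {_norm_symbol(g) for g in collection[name]} & bg
        K = len(members)
        ov = len(members & query)
        if ov < min_overlap:
            continue
        if K == N:
            p = 1.0  # universe == set: no enrichment is definable
        else:
            p = float(stats.hypergeom.sf(ov - 1, N, K, q))
        expected = K * q / N
        rows.append(
            {
                "set": name,
                "overlap": ov,
                "set_size": K,
                "query_size": q,
                "p": p,
                "ratio": ov / expected if expected > 0 else math.nan,
            }
        )
    df = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "query_size", "p", "ratio"])
    if not df.empty:
        df["fdr"] = bh_fdr(df["p"].to_numpy())
        df["significant"] = df["fdr"] < fdr_max
        df = df.sort_values(["fdr", "p", "set"]).reset_index(drop=True)
    return df


def triangulate(
    set_a: set[str], set_b: set[str], set_c: set[str], rule: str = "default"
) -> pd.DataFrame:
    """Converging-evidence table across the three target sets.

    Default rule: converging iff in a AND (b OR c) — set a (the
    pQTL-associated proteins) is mandatory.  ``rule="strict"`` requires
    the three-way intersection.
    """
    if rule not in {"default", "strict"}:
        raise ValueError("rule must be 'default' or 'strict'")
    a = {_norm_symbol(g) for g in set_a}
    b = {_norm_symbol(g) for g in set_b}
    c = {_norm_symbol(g) for g in set_c}
    rows = []
    for g in sorted(a | b | c):
        ia, ib, ic = g in a, g in b, g in c
        if rule == "strict":
            conv = ia and ib and ic
        else:
            conv = ia and (ib or ic)
        rows.append(
            {"protein": g, "in_set_a": ia, "in_set_b": ib, "in_set_c": ic,
             "converging": conv}
        )
    return pd.DataFrame(
        rows, columns=["protein", "in_set_a", "in_set_b", "in_set_c", "converging"]
    )


def genotype_ancova(
    abundance: np.ndarray,
    genotype: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
) -> dict:
    """ANCOVA of protein abundance across genotype groups.

    Model: abundance ~ C(genotype) + age + sex + age:sex.  Returns the
    genotype-factor F-test and all pairwise genotype contrasts with
    two-sided t p-values.  Genotype levels with fewer than 2 samples
    are dropped with a warning.
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(abundance, dtype=float),
            "geno": pd.Categorical(genotype),
            "age": np.asarray(age, dtype=float),
            "sex": np.asarray(sex, dtype=float),
        }
    )
    counts = df["geno"].value_counts()
    small = counts[counts < 2].index.tolist()
    if small:
        logger.warning("genotype_ancova: dropping levels with < 2 samples: %s", small)
        df = df[~df["geno"].isin(small)]
        df["geno"] = df["geno"].cat.remove_unused_categories()
    levels = list(df["geno"].cat.categories)
    if len(levels) < 2:
        raise ValueError("need >= 2 genotype levels with >= 2 samples each")
    model = smf.ols("y ~ C(geno) + age + sex + age:sex", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    f_p = float(anova.loc["C(geno)", "PR(>F)"])
    f_stat = float(anova.loc["C(geno)", "F"])

    contrasts = {}
    names = model.params.index
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a, b = levels[i], levels[j]
            vec = np.zeros(len(names))
            for k, nm in enumerate(names):
                if nm == f"C(geno)[T.{b}]":
                    vec[k] = 1.0
                elif nm == f"C(geno)[T.{a}]":
                    vec[k] = -1.0
            tt = model.t_test(vec)
            contrasts[f"{a}_vs_{b}"] = {
                "diff": float(np.atleast_1d(tt.effect)[0]),
                "se": float(np.atleast_1d(tt.sd.squeeze())[0]),
                "p": float(np.atleast_1d(tt.pvalue)[0]),
            }
    return {"f_stat": f_stat, "f_p": f_p, "contrasts": contrasts, "n": len(df)}


def carrier_frequency_test(
    case_carriers: int,
    case_noncarriers: int,
    control_carriers: int,
    control_noncarriers: int,
) -> tuple[float | str, float]:
    """2x2 Fisher exact test (two-sided) plus the sample odds ratio.

    Returns (odds ratio or "undefined" on a zero margin, p-value).
    """
    table = np.array(
        [[case_carriers, case_noncarriers], [control_carriers, control_noncarriers]]
    )
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    odds: float | str
    if (table == 0).any():
        odds = "undefined"
    else:
        odds = (case_carriers * control_noncarriers) / (
            case_noncarriers * control_carriers
        )
    return odds, float(p)


def _strip_chr(c: str) -> str:
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


def map_variants_to_loops(
    variants: pd.DataFrame, loops: pd.DataFrame
) -> pd.DataFrame:
    """Link variants to distal genes through chromatin-loop anchors.

    A variant inside anchor 1 (half-open [start, end), 0-based; variant
    positions are 1-based and converted) links to the genes annotated
    to anchor 2 and vice versa, labeled with the loop's cell type.
    Chromosome names are normalized ("chr1" == "1").  Output rows are
    deduplicated and sorted, so loop record order is immaterial.
    """
    rows = []
    for _, v in variants.iterrows():
        pos0 = int(v["pos"]) - 1
        vchrom = _strip_chr(v["chrom"])
        for _, lp in loops.iterrows():
            for near, far in ((1, 2), (2, 1)):
                if _strip_chr(lp[f"chrom{near}"]) != vchrom:
                    continue
                if not (int(lp[f"start{near}"]) <= pos0 < int(lp[f"end{near}"])):
                    continue
                genes = str(lp[f"genes{far}"])
                for gene in genes.split(";"):
                    gene = gene.strip()
                    if gene:
                        rows.append(
                            {
                                "variant_id": v["variant_id"],
                                "distal_gene": _norm_symbol(gene),
                                "cell_type": lp["cell_type"],
                            }
                        )
    df = pd.DataFrame(rows, columns=["variant_id", "distal_gene", "cell_type"])
    return (
        df.drop_duplicates()
        .sort_values(["variant_id", "distal_gene", "cell_type"])
        .reset_index(drop=True)
    )


def set_overlap_report(set_a: set[str], set_b: set[str], universe_size: int) -> dict:
    """Formatted overlap report (thin wrapper over the Fisher overlap test)."""
    ov, p, odds = netmod.overlap_test(set_a, set_b, universe_size)
    return {
        "shared": ov,
        "a_only": len(set(set_a)) - ov,
        "b_only": len(set(set_b)) - ov,
        "p": p,
        "odds_ratio": odds,
        "universe": universe_size,
    }
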