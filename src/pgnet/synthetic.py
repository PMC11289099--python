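"""Synthetic cohort generator.

Emulates the statistical structure the downstream analyses assume:

* LD-blocked genotypes — within a block, per-haplotype latent Gaussians
  follow a first-order autoregressive correlation ``rho`` and are
  thresholded at the allele frequency; the two haplotypes sum to a
  dosage in {0, 1, 2}.  Blocks are mutually independent.
* a liability-threshold binary trait with sparse causal variants and a
  heritability ``h2_liability`` on the liability scale;
* protein abundances (NPX-like, continuous) with planted cis and trans
  genetic effects plus age/sex covariate terms and Gaussian noise;
* a scale-free PPI network with a planted connected subnetwork whose
  genes carry the disease signal (so the module search has a target);
* gene-set collections and chromatin-loop anchor pairs consistent with
  the same gene universe.

Every generator is a pure function of its spec and seed.  A single
global seed fans out to per-component child seeds through a documented
counter scheme (:func:`component_rng`), so stages can be regenerated
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

MISSING = -1  # sentinel for missing dosage

#: fixed component indices for seed fan-out (order is part of the contract)
COMPONENT_INDEX = {
    "genotypes": 0,
    "phenotype": 1,
    "proteins": 2,
    "ppi": 3,
    "annotation": 4,
    "missingness": 5,
    "gene_sets": 6,
    "loops": 7,
}

#: fixed covariate loadings on the disease liability (standardized scale)
LIABILITY_LOADINGS = {"age": 0.10, "sex": 0.10}

#: fixed covariate effects on every protein (standardized age, 0/1 sex)
PROTEIN_COVARIATE_EFFECTS = {"age": 0.20, "sex": 0.30, "age_sex": 0.05}


def component_rng(seed: int, component: str) -> np.random.Generator:
    """Child RNG for one pipeline component.

    Children are derived as ``SeedSequence(seed, spawn_key=(index,))``
    with the fixed index from :data:`COMPONENT_INDEX`.
    """
    idx = COMPONENT_INDEX[component]
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(idx,)))


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort."""

    n_samples: int = 2000
    n_variants: int = 240
    n_blocks: int = 12
    rho: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal_disease: int = 8
    h2_liability: float = 0.3
    prevalence: float = 0.1
    n_proteins: int = 40
    cis_effect_sd: float = 0.4
    trans_effect_sd: float = 0.15
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    n_pcs: int = 4
    n_cis_per_protein: int = 1
    n_trans_per_protein: int = 1
    # PPI layer
    n_ppi_nodes: int = 300
    ppi_attach_m: int = 2
    planted_module_size: int = 12
    planted_fraction: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_causal_disease > self.n_variants:
            raise ValueError("n_causal_disease exceeds n_variants")
        if not (0.0 <= self.h2_liability < 1.0):
            raise ValueError("h2_liability must lie in [0, 1)")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")
        if self.prevalence * self.n_samples < 1:
            raise ValueError("prevalence * n_samples must be >= 1")
        for name in ("cis_effect_sd", "trans_effect_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.planted_module_size >= self.n_ppi_nodes:
            raise ValueError("planted_module_size must be < n_ppi_nodes")
        if self.ppi_attach_m >= self.n_ppi_nodes:
            raise ValueError("attach_m must be < n_ppi_nodes")


@dataclass
class SyntheticCohort:
    """Bundle of all generated inputs plus the ground truth."""

    spec: CohortSpec
    genotypes: np.ndarray  # samples x variants, int8, MISSING sentinel
    variant_table: pd.DataFrame
    phenotype: np.ndarray  # 0/1 per sample
    covariates: pd.DataFrame
    proteins: pd.DataFrame  # samples x proteins
    gene_annotation: pd.DataFrame  # BED-like, one row per gene
    protein_genes: dict[str, str]  # protein -> coding gene
    ppi_edges: list[tuple[str, str]]
    planted_module: set[str]
    gene_sets: dict[str, set[str]]
    loops: pd.DataFrame
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(
    spec: CohortSpec, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """LD-blocked dosages plus the variant table.

    Two independent haplotypes per sample; each is an AR(1) latent
    Gaussian thresholded at ``Phi^-1(maf)``, so adjacent variants in a
    block share LD controlled by ``rho``.
    """
    spec.validate()
    if rng is None:
        rng = component_rng(spec.seed, "genotypes")
    n, m = spec.n_samples, spec.n_variants
    block_sizes = np.full(spec.n_blocks, m // spec.n_blocks)
    block_sizes[: m % spec.n_blocks] += 1

    # the variant panel (frequencies + allele labels) is a fixed reference
    # shared by every cohort of the same shape, so that multi-cohort
    # meta-analysis sees consistent alleles; genotypes still vary by seed
    panel_rng = np.random.default_rng(
        np.random.SeedSequence(0x5EED9A7E1, spawn_key=(m,))
    )
    lo, hi = spec.maf_range
    mafs = panel_rng.uniform(lo, hi, size=m)
    thresholds = norm.ppf(mafs)

    geno = np.zeros((n, m), dtype=np.int8)
    col = 0
    blocks = np.zeros(m, dtype=int)
    for b, size in enumerate(block_sizes):
        for _hap in range(2):
            z = np.empty((n, size))
            z[:, 0] = rng.standard_normal(n)
            scale = np.sqrt(1.0 - spec.rho**2)
            for j in range(1, size):
                z[:, j] = spec.rho * z[:, j - 1] + scale * rng.standard_normal(n)
            geno[:, col : col + size] += (
                z < thresholds[col : col + size]
            ).astype(np.int8)
        blocks[col : col + size] = b
        col += size

    if spec.missing_rate > 0:
        mrng = component_rng(spec.seed, "missingness")
        mask = mrng.random(geno.shape) < spec.missing_rate
        geno[mask] = MISSING

    chrom = (blocks % 22 + 1).astype(str)
    pos = np.zeros(m, dtype=int)
    for b in range(spec.n_blocks):
        idx = np.flatnonzero(blocks == b)
        base = 10_000 + 2_000_000 * (b // 22)
        pos[idx] = base + 2000 * np.arange(idx.size)
    alleles_ref = np.array(["A", "C", "G", "T"])
    ea = alleles_ref[panel_rng.integers(0, 4, size=m)]
    shift = panel_rng.integers(1, 4, size=m)  # other allele always differs
    oa = alleles_ref[(np.searchsorted(alleles_ref, ea) + shift) % 4]
    variant_table = pd.DataFrame(
        {
            "variant_id": [f"v{i:05d}" for i in range(m)],
            "chrom": chrom,
            "pos": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "frequency": mafs,
            "block": blocks,
        }
    )
    return geno, variant_table


# ---------------------------------------------------------------------------
# phenotype


def simulate_phenotype(
    genotypes: np.ndarray,
    spec: CohortSpec,
    causal_variants: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, pd.DataFrame, dict]:
    """Liability-threshold case/control trait plus covariates.

    liability = sqrt(h2) * standardized causal score
              + small fixed covariate loadings + sqrt(1-h2) * noise;
    a sample is a case iff its liability exceeds the (1 - prevalence)
    normal quantile of the total liability variance.
    """
    spec.validate()
    if rng is None:
        rng = component_rng(spec.seed, "phenotype")
    n = genotypes.shape[0]

    age = rng.uniform(40, 70, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    yob = rng.integers(1940, 1971, size=n).astype(float)
    pcs = rng.standard_normal((n, spec.n_pcs))
    covariates = pd.DataFrame({"age": age, "sex": sex, "yob": yob})
    for k in range(spec.n_pcs):
        covariates[f"pc{k + 1}"] = pcs[:, k]

    if causal_variants is None:
        causal_variants = rng.choice(
            genotypes.shape[1], size=spec.n_causal_disease, replace=False
        )
    causal_variants = np.asarray(sorted(causal_variants))

    dos = genotypes[:, causal_variants].astype(float)
    dos[dos == MISSING] = np.nan
    colmean = np.nanmean(dos, axis=0)
    dos = np.where(np.isnan(dos), colmean, dos)
    score = ((dos - colmean) / np.maximum(dos.std(axis=0), 1e-12)).sum(axis=1)
    sd = score.std()
    g_std = score / sd if sd > 0 else np.zeros(n)

    age_std = (age - age.mean()) / age.std()
    sex_c = sex - sex.mean()
    load = LIABILITY_LOADINGS
    cov_term = load["age"] * age_std + load["sex"] * sex_c / max(sex.std(), 1e-12)
    h2 = spec.h2_liability
    liability = (
        np.sqrt(h2) * g_std + cov_term + np.sqrt(1.0 - h2) * rng.standard_normal(n)
    )
    total_var = 1.0 + sum(v**2 for v in load.values())
    threshold = norm.isf(spec.prevalence) * np.sqrt(total_var)
    phenotype = (liability > threshold).astype(np.int8)

    truth = {
        "causal_variants": causal_variants,
        "h2_liability": h2,
        "liability_threshold": float(threshold),
        "covariate_loadings": dict(load),
    }
    return phenotype, covariates, truth


# ---------------------------------------------------------------------------
# gene annotation


def simulate_gene_annotation(
    variant_table: pd.DataFrame,
    genes: Sequence[str],
    rng: np.random.Generator,
    span_range: tuple[int, int] = (2, 4),
) -> pd.DataFrame:
    """Assign each gene a BED-like interval covering consecutive variants.

    Intervals are 0-based half-open and always cover at least
    ``span_range[0]`` variants of a single LD block; genes may overlap.
    """
    rows = []
    by_block = variant_table.groupby("block", sort=True)
    block_ids = list(by_block.groups)
    for gene in genes:
        b = block_ids[int(rng.integers(0, len(block_ids)))]
        sub = by_block.get_group(b).sort_values("pos")
        span = int(rng.integers(span_range[0], span_range[1] + 1))
        span = min(span, len(sub))
        start_i = int(rng.integers(0, len(sub) - span + 1))
        first = sub.iloc[start_i]
        last = sub.iloc[start_i + span - 1]
        rows.append(
            {
                "chrom": first["chrom"],
                "start": int(first["pos"]) - 1,  # 0-based, covers first variant
                "end": int(last["pos"]),  # half-open, covers last variant
                "gene": gene,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# proteins


def simulate_proteins(
    genotypes: np.ndarray,
    covariates: pd.DataFrame,
    spec: CohortSpec,
    gene_annotation: pd.DataFrame,
    variant_table: pd.DataFrame,
    protein_genes: dict[str, str],
    rng: np.random.Generator | None = None,
    preferred_cis: set[int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NPX-like protein abundances with planted cis/trans genetic effects.

    Each protein is the sum of its cis effects (variants inside the
    coding gene's interval), trans effects (variants elsewhere), fixed
    age/sex covariate terms, and N(0, noise_sd^2) residual noise.
    Returns the abundance matrix and the truth table of nonzero effects.
    """
    spec.validate()
    if rng is None:
        rng = component_rng(spec.seed, "proteins")
    ann = gene_annotation.set_index("gene")
    n = genotypes.shape[0]

    age = covariates["age"].to_numpy()
    sex = covariates["sex"].to_numpy()
    age_std = (age - age.mean()) / age.std()
    eff = PROTEIN_COVARIATE_EFFECTS
    cov_term = eff["age"] * age_std + eff["sex"] * sex + eff["age_sex"] * age_std * sex

    dos = genotypes.astype(float)
    dos[dos == MISSING] = np.nan
    colmean = np.nanmean(dos, axis=0)
    dos = np.where(np.isnan(dos), colmean, dos)

    vt = variant_table
    abundances = {}
    truth_rows = []
    for protein, gene in protein_genes.items():
        if gene not in ann.index:
            raise KeyError(f"protein {protein} has no gene annotation for {gene}")
        g = ann.loc[gene]
        in_gene = (
            (vt["chrom"] == g["chrom"])
            & (vt["pos"] > int(g["start"]))  # 0-based half-open interval
            & (vt["pos"] <= int(g["end"]))
        ).to_numpy()
        cis_pool = np.flatnonzero(in_gene)
        trans_pool = np.flatnonzero(~in_gene)
        y = cov_term + rng.normal(0.0, spec.noise_sd, size=n)
        if spec.cis_effect_sd > 0 and cis_pool.size:
            k = min(spec.n_cis_per_protein, cis_pool.size)
            # cis effects sit on disease-causal variants when the gene has
            # one (genetically mediated protein), else anywhere in the gene
            pool = cis_pool
            if preferred_cis:
                pref = np.array([v for v in cis_pool if v in preferred_cis])
                if pref.size >= k:
                    pool = pref
            for v in rng.choice(pool, size=k, replace=False):
                beta = rng.normal(0.0, spec.cis_effect_sd)
                y = y + beta * dos[:, v]
                truth_rows.append(
                    {
                        "variant_id": vt["variant_id"].iloc[v],
                        "protein": protein,
                        "beta": beta,
                        "kind": "cis",
                    }
                )
        if spec.trans_effect_sd > 0 and trans_pool.size:
            k = min(spec.n_trans_per_protein, trans_pool.size)
            for v in rng.choice(trans_pool, size=k, replace=False):
                beta = rng.normal(0.0, spec.trans_effect_sd)
                y = y + beta * dos[:, v]
                truth_rows.append(
                    {
                        "variant_id": vt["variant_id"].iloc[v],
                        "protein": protein,
                        "beta": beta,
                        "kind": "trans",
                    }
                )
        abundances[protein] = y

    proteins = pd.DataFrame(abundances)
    truth = pd.DataFrame(
        truth_rows, columns=["variant_id", "protein", "beta", "kind"]
    )
    return proteins, truth


# ---------------------------------------------------------------------------
# PPI network


def simulate_ppi(
    n_nodes: int,
    attach_m: int = 2,
    planted_module_size: int = 10,
    seed: int = 0,
    node_names: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str]], set[str]]:
    """Scale-free PPI by preferential attachment, plus a planted module.

    Construction: start from two nodes joined by one edge; each new node
    attaches ``min(attach_m, #existing)`` distinct edges to existing
    nodes with probability proportional to degree.  For ``attach_m = 2``
    this yields exactly ``2*(n-2) + 1`` edges.  The planted module is a
    connected node set grown by uniform neighbor expansion.
    """
    if attach_m >= n_nodes:
        raise ValueError("attach_m must be < n_nodes")
    if planted_module_size >= n_nodes:
        raise ValueError("planted_module_size must be < n_nodes")
    if rng is None:
        rng = component_rng(seed, "ppi")
    if node_names is None:
        node_names = [f"G{i:04d}" for i in range(n_nodes)]
    if len(node_names) != n_nodes:
        raise ValueError("node_names length must equal n_nodes")

    degree = np.zeros(n_nodes, dtype=float)
    edges_idx: list[tuple[int, int]] = [(0, 1)]
    degree[0] = degree[1] = 1
    adjacency: dict[int, set[int]] = {0: {1}, 1: {0}}
    for t in range(2, n_nodes):
        k = min(attach_m, t)
        probs = degree[:t] / degree[:t].sum()
        targets = rng.choice(t, size=k, replace=False, p=probs)
        adjacency[t] = set()
        for u in sorted(int(x) for x in targets):
            edges_idx.append((u, t))
            adjacency[t].add(u)
            adjacency[u].add(t)
            degree[u] += 1
            degree[t] += 1

    # grow a connected planted set by uniform neighbor expansion
    start = int(rng.integers(0, n_nodes))
    planted = {start}
    frontier = set(adjacency[start])
    while len(planted) < planted_module_size and frontier:
        v = sorted(frontier)[int(rng.integers(0, len(frontier)))]
        planted.add(v)
        frontier |= adjacency[v]
        frontier -= planted

    edges = [(node_names[a], node_names[b]) for a, b in edges_idx]
    return edges, {node_names[v] for v in planted}


# ---------------------------------------------------------------------------
# gene sets and chromatin loops


def simulate_gene_sets(
    genes: Sequence[str],
    planted: set[str],
    rng: np.random.Generator,
    n_sets: int = 20,
    set_size_range: tuple[int, int] = (10, 40),
) -> dict[str, set[str]]:
    """Random gene sets plus one set concentrated on the planted module."""
    genes = list(genes)
    sets: dict[str, set[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(set_size_range[0], set_size_range[1] + 1))
        members = rng.choice(len(genes), size=min(size, len(genes)), replace=False)
        sets[f"SET_{i:03d}"] = {genes[j] for j in members}
    extra = rng.choice(len(genes), size=min(8, len(genes)), replace=False)
    sets["PLANTED_PATHWAY"] = set(planted) | {genes[j] for j in extra}
    return sets


def simulate_loops(
    variant_table: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    rng: np.random.Generator,
    n_loops: int = 12,
    anchor_width: int = 1500,
    cell_types: Sequence[str] = ("neuron", "oligodendrocyte", "microglia"),
    focus_variants: Sequence[str] = (),
) -> pd.DataFrame:
    """Chromatin-loop anchor pairs linking variant loci to distal genes.

    Anchor 1 covers a variant (preferentially one of ``focus_variants``,
    e.g. risk loci, for half the loops); anchor 2 covers a gene on the
    same chromosome (distal regulation target).
    """
    rows = []
    ann = gene_annotation
    focus = variant_table[variant_table["variant_id"].isin(set(focus_variants))]
    for i in range(n_loops):
        if len(focus) and i % 2 == 0:
            v = focus.iloc[int(rng.integers(0, len(focus)))]
        else:
            v = variant_table.iloc[int(rng.integers(0, len(variant_table)))]
        same_chrom = ann[ann["chrom"] == v["chrom"]]
        if same_chrom.empty:
            continue
        g = same_chrom.iloc[int(rng.integers(0, len(same_chrom)))]
        a1_start = int(v["pos"]) - 1 - anchor_width // 2
        rows.append(
            {
                "chrom1": v["chrom"],
                "start1": max(a1_start, 0),
                "end1": max(a1_start, 0) + anchor_width,
                "chrom2": g["chrom"],
                "start2": int(g["start"]),
                "end2": int(g["end"]),
                "cell_type": cell_types[int(rng.integers(0, len(cell_types)))],
                "genes1": "",
                "genes2": g["gene"],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration


def simulate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full cohort: genotypes, trait, proteins, PPI, sets, loops.

    Disease causal variants are drawn preferentially (fraction
    ``planted_fraction``) from within the gene windows of the planted
    PPI module, so the module search has a recoverable target.
    """
    spec.validate()
    genotypes, variant_table = simulate_genotypes(spec)

    gene_names = [f"G{i:04d}" for i in range(spec.n_ppi_nodes)]
    ann_rng = component_rng(spec.seed, "annotation")
    gene_annotation = simulate_gene_annotation(variant_table, gene_names, ann_rng)

    ppi_edges, planted = simulate_ppi(
        spec.n_ppi_nodes,
        spec.ppi_attach_m,
        spec.planted_module_size,
        seed=spec.seed,
        node_names=gene_names,
    )

    # causal variants biased into planted-module gene windows
    rng = component_rng(spec.seed, "phenotype")
    ann = gene_annotation.set_index("gene")
    planted_variant_idx: list[int] = []
    vt = variant_table
    for gene in sorted(planted):
        g = ann.loc[gene]
        hit = (
            (vt["chrom"] == g["chrom"])
            & (vt["pos"] > int(g["start"]))
            & (vt["pos"] <= int(g["end"]))
        )
        planted_variant_idx.extend(np.flatnonzero(hit.to_numpy()))
    planted_variant_idx = sorted(set(planted_variant_idx))
    n_from_planted = min(
        int(round(spec.planted_fraction * spec.n_causal_disease)),
        len(planted_variant_idx),
    )
    chosen = list(
        rng.choice(planted_variant_idx, size=n_from_planted, replace=False)
    ) if n_from_planted else []
    rest_pool = np.setdiff1d(np.arange(spec.n_variants), chosen)
    n_rest = spec.n_causal_disease - len(chosen)
    chosen += list(rng.choice(rest_pool, size=n_rest, replace=False))
    causal = np.array(sorted(int(c) for c in chosen))

    phenotype, covariates, pheno_truth = simulate_phenotype(
        genotypes, spec, causal_variants=causal, rng=rng
    )

    # the measured panel covers the planted-module genes first (their
    # proteins carry the genetically mediated signal), then fills up
    panel_genes = sorted(planted) + [g for g in gene_names if g not in planted]
    panel_genes = panel_genes[: spec.n_proteins]
    protein_genes = {g: g for g in panel_genes}
    proteins, pqtl_truth = simulate_proteins(
        genotypes, covariates, spec, gene_annotation, variant_table, protein_genes,
        preferred_cis=set(int(v) for v in causal),
    )

    gs_rng = component_rng(spec.seed, "gene_sets")
    gene_sets = simulate_gene_sets(gene_names, planted, gs_rng)
    loop_rng = component_rng(spec.seed, "loops")
    causal_ids = variant_table["variant_id"].iloc[causal].tolist()
    loops = simulate_loops(
        variant_table, gene_annotation, loop_rng, focus_variants=causal_ids
    )

    truth = dict(pheno_truth)
    truth["pqtl_effects"] = pqtl_truth
    truth["planted_module"] = set(planted)
    truth["protein_covariate_effects"] = dict(PROTEIN_COVARIATE_EFFECTS)

    cohort = SyntheticCohort(
        spec=spec,
        genotypes=genotypes,
        variant_table=variant_table,
        phenotype=phenotype,
        covariates=covariates,
        proteins=proteins,
        gene_annotation=gene_annotation,
        protein_genes=protein_genes,
        ppi_edges=ppi_edges,
        planted_module=set(planted),
        gene_sets=gene_sets,
        loops=loops,
        truth=truth,
    )
    _check_cohort(cohort)
    return cohort


def _check_cohort(c: SyntheticCohort) -> None:
    """Internal consistency checks (dimensions, truth indices, frequencies)."""
    n, m = c.genotypes.shape
    assert len(c.phenotype) == n and len(c.covariates) == n
    assert len(c.proteins) == n
    assert len(c.variant_table) == m
    assert all(0 <= v < m for v in c.truth["causal_variants"])
    dos = c.genotypes.astype(float)
    dos[dos == MISSING] = np.nan
    emp = np.nanmean(dos, axis=0) / 2.0
    f = c.variant_table["frequency"].to_numpy()
    sd = np.sqrt(f * (1 - f) / (2 * n))
    if not np.all(np.abs(emp - f) < 5 * sd + 1e-9):
        raise AssertionError("empirical allele frequency drifted > 5 SD from spec")
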