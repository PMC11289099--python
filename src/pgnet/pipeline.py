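"""End-to-end pipeline orchestration with seeding, logging, and provenance.

Ten stages run in dependency order over a simulated (or supplied)
cohort pair:

  1. simulate     — two synthetic cohorts sharing causal architecture
  2. gwas_a       — per-variant logistic scan, cohort A
  3. gwas_b       — per-variant logistic scan, cohort B
  4. meta         — fixed-effects inverse-variance meta-analysis
  5. pqtl         — pQTL scan, cis/trans classification, GWAS intersection
  6. gene_scores  — LD-corrected gene-based scores
  7. modules      — dense-module search, normalization, top-1% selection
  8. neighbors    — first-degree network + permutation enrichment
  9. causal       — MR, pleiotropy screen, coloc, fine-mapping
 10. evidence     — pathway enrichment, triangulation, loop mapping

Each stage writes TSV outputs plus a manifest entry (parameters, seed,
content hashes, row counts).  Re-running with an intact manifest skips
completed stages unless forced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, causal, enrich, genescore, io, netmod, pqtl, synthetic

logger = logging.getLogger(__name__)

STAGES = [
    "simulate",
    "gwas_a",
    "gwas_b",
    "meta",
    "pqtl",
    "gene_scores",
    "modules",
    "neighbors",
    "causal",
    "evidence",
]


@dataclasses.dataclass
class PipelineConfig:
    out_dir: str = "pgnet_run"
    seed: int = 0
    cohort: synthetic.CohortSpec = dataclasses.field(
        default_factory=synthetic.CohortSpec
    )
    # stage parameters (defaults follow the analysis conventions)
    alpha_gwas: float = 5e-8
    alpha_pqtl: float = 5e-8
    cis_window_bp: int = 1000
    gene_flank_bp: int = 0
    d: int = 2
    r: float = 0.1
    top_fraction: float = 0.01
    b_norm: int = 2000
    b_perm: int = 10_000
    r2_clump: float = 0.001
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    finemap_window_bp: int = 500_000
    fdr_max: float = 0.05
    triangulation_rule: str = "default"
    mr_alpha_instruments: float = 1e-4  # instrument significance on synthetic scale

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_raw = raw.pop("cohort", {})
        cfg = cls(**{k: v for k, v in raw.items() if k in _CONFIG_FIELDS})
        unknown = [k for k in raw if k not in _CONFIG_FIELDS]
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        spec_fields = {f.name for f in dataclasses.fields(synthetic.CohortSpec)}
        bad = [k for k in cohort_raw if k not in spec_fields]
        if bad:
            raise ValueError(f"unknown cohort keys: {bad}")
        if "maf_range" in cohort_raw:
            cohort_raw["maf_range"] = tuple(cohort_raw["maf_range"])
        cfg.cohort = synthetic.CohortSpec(**cohort_raw)
        return cfg


_CONFIG_FIELDS = {f.name for f in dataclasses.fields(PipelineConfig)} - {"cohort"}


def validate_config(config: PipelineConfig) -> list[str]:
    """Range/schema checks; a nonempty issue list blocks the run."""
    issues = []
    try:
        config.cohort.validate()
    except ValueError as exc:
        issues.append(f"cohort: {exc}")
    if config.r <= 0:
        issues.append("r: increment rate must be > 0")
    if config.d < 1:
        issues.append("d: neighbor order must be >= 1")
    if not (0 < config.top_fraction <= 1):
        issues.append("top_fraction: must lie in (0, 1]")
    for name in ("alpha_gwas", "alpha_pqtl", "fdr_max"):
        v = getattr(config, name)
        if not (0 < v < 1):
            issues.append(f"{name}: must lie in (0, 1)")
    for name in ("coloc_p1", "coloc_p2", "coloc_p12"):
        v = getattr(config, name)
        if not (0 < v < 1):
            issues.append(f"{name}: must lie in (0, 1)")
    if config.b_norm < 100:
        issues.append("b_norm: must be >= 100")
    if config.b_perm < 100:
        issues.append("b_perm: must be >= 100")
    if config.triangulation_rule not in {"default", "strict"}:
        issues.append("triangulation_rule: must be 'default' or 'strict'")
    return issues


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRunner:
    """Stage executor holding in-memory state and the run manifest."""

    def __init__(self, config: PipelineConfig, force: bool = False):
        issues = validate_config(config)
        if issues:
            raise ValueError("invalid config: " + "; ".join(issues))
        self.config = config
        self.force = force
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.manifest = self._load_manifest()
        self.state: dict = {}

    def _load_manifest(self) -> dict:
        if self.manifest_path.exists() and not self.force:
            with open(self.manifest_path) as fh:
                return json.load(fh)
        return {"stages": {}}

    def _save_manifest(self) -> None:
        with open(self.manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True, default=str)

    def _stage_done(self, name: str) -> bool:
        entry = self.manifest["stages"].get(name)
        if entry is None or self.force:
            return False
        return all(Path(p).exists() for p in entry["outputs"])

    def _record(self, name: str, params: dict, outputs: list[Path], counts: dict) -> None:
        self.manifest["stages"][name] = {
            "params": params,
            "seed": self.config.seed,
            "outputs": [str(p) for p in outputs],
            "hashes": {p.name: _sha256(p) for p in outputs},
            "row_counts": counts,
            "completed_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        self._save_manifest()

    # -- stages ------------------------------------------------------------

    def run(self, until: str | None = None) -> dict:
        stages = STAGES
        if until is not None:
            if until not in STAGES:
                raise ValueError(f"unknown stage '{until}'")
            stages = STAGES[: STAGES.index(until) + 1]
        for name in stages:
            fn = getattr(self, f"stage_{name}")
            if self._stage_done(name) and self._can_skip(name):
                logger.info("stage %s: up to date, skipped", name)
                fn(skip=True)
                continue
            logger.info("stage %s: running", name)
            try:
                fn(skip=False)
            except Exception:
                logger.exception("stage %s failed", name)
                raise RuntimeError(f"pipeline halted at stage '{name}'")
        return self.manifest

    def _can_skip(self, name: str) -> bool:
        # stages always rebuild in-memory state from their outputs
        return True

    def stage_simulate(self, skip: bool = False) -> None:
        cfg = self.config
        spec_a = dataclasses.replace(cfg.cohort, seed=cfg.seed)
        spec_b = dataclasses.replace(cfg.cohort, seed=cfg.seed + 1_000_003)
        cohort_a = synthetic.simulate_cohort(spec_a)
        # cohort B shares the causal variants of A (same disease architecture)
        geno_b, vt_b = synthetic.simulate_genotypes(spec_b)
        rng_b = synthetic.component_rng(spec_b.seed, "phenotype")
        pheno_b, cov_b, _ = synthetic.simulate_phenotype(
            geno_b, spec_b, causal_variants=cohort_a.truth["causal_variants"],
            rng=rng_b,
        )
        self.state.update(
            cohort=cohort_a,
            geno_b=geno_b,
            vt_b=vt_b,
            pheno_b=pheno_b,
            cov_b=cov_b,
        )
        if skip:
            return
        out = self.out
        io.write_tsv(cohort_a.variant_table, out / "variants_a.tsv")
        io.write_gene_annotation(cohort_a.gene_annotation, out / "genes.tsv")
        io.write_edge_list(cohort_a.ppi_edges, out / "ppi_edges.tsv")
        io.write_gmt(cohort_a.gene_sets, out / "gene_sets.gmt")
        io.write_loops(cohort_a.loops, out / "loops.tsv")
        cov = cohort_a.covariates.copy()
        cov["phenotype"] = cohort_a.phenotype
        io.write_tsv(cov, out / "phenotype_covariates_a.tsv")
        io.write_tsv(cohort_a.truth["pqtl_effects"], out / "truth_pqtl.tsv")
        outputs = [
            out / "variants_a.tsv", out / "genes.tsv", out / "ppi_edges.tsv",
            out / "gene_sets.gmt", out / "loops.tsv",
            out / "phenotype_covariates_a.tsv", out / "truth_pqtl.tsv",
        ]
        self._record(
            "simulate",
            {"cohort": dataclasses.asdict(spec_a)},
            outputs,
            {
                "n_samples": spec_a.n_samples,
                "n_variants": spec_a.n_variants,
                "n_cases_a": int(cohort_a.phenotype.sum()),
                "n_cases_b": int(pheno_b.sum()),
            },
        )

    def _gwas(self, geno, vt, pheno, cov, label: str, skip: bool) -> None:
        path = self.out / f"gwas_{label}.tsv"
        if skip and path.exists():
            self.state[f"gwas_{label}"] = io.read_sumstats(path)
            return
        res = assoc.gwas_scan(geno, vt, pheno, cov)
        self.state[f"gwas_{label}"] = res
        io.write_sumstats(res, path)
        self._record(f"gwas_{label}", {"covariates": "sex+yob+PCs"}, [path],
                     {"n_variants_tested": len(res)})

    def stage_gwas_a(self, skip: bool = False) -> None:
        c = self.state["cohort"]
        self._gwas(c.genotypes, c.variant_table, c.phenotype, c.covariates, "a", skip)

    def stage_gwas_b(self, skip: bool = False) -> None:
        self._gwas(
            self.state["geno_b"], self.state["vt_b"], self.state["pheno_b"],
            self.state["cov_b"], "b", skip,
        )

    def stage_meta(self, skip: bool = False) -> None:
        path = self.out / "meta.tsv"
        if skip and path.exists():
            self.state["meta"] = io.read_tsv(path, dtype={"chrom": str})
            self.state["gwas_hits"] = assoc.genomewide_significant(
                self.state["meta"], self.config.alpha_gwas
            )
            return
        meta = assoc.meta_fixed(self.state["gwas_a"], self.state["gwas_b"])
        hits = assoc.genomewide_significant(meta, self.config.alpha_gwas)
        self.state["meta"] = meta
        self.state["gwas_hits"] = hits
        io.write_tsv(meta, path)
        self._record("meta", {"alpha": self.config.alpha_gwas}, [path],
                     {"n_variants": len(meta), "n_hits": len(hits)})

    def stage_pqtl(self, skip: bool = False) -> None:
        c = self.state["cohort"]
        cfg = self.config
        path = self.out / "pqtl.tsv"
        if skip and path.exists():
            self.state["pqtl"] = io.read_tsv(path)
        else:
            records = pqtl.pqtl_scan(
                c.proteins, c.genotypes, c.covariates, c.variant_table,
                alpha=cfg.alpha_pqtl,
            )
            records = pqtl.classify_cis_trans(
                records, c.variant_table, c.gene_annotation, c.protein_genes,
                window_bp=cfg.cis_window_bp,
            )
            self.state["pqtl"] = records
            io.write_tsv(records, path)
        records = self.state["pqtl"]
        hits = set(self.state["gwas_hits"]["variant_id"])
        pairs, proteins = pqtl.intersect_gwas_pqtl(hits, records)
        self.state["pqtl_pairs"] = pairs
        self.state["pqtl_proteins"] = proteins
        arch = pqtl.architecture_summary(records) if len(records) else None
        self.state["architecture"] = arch
        if skip:
            return
        pairs_path = self.out / "gwas_pqtl_pairs.tsv"
        io.write_tsv(pairs, pairs_path)
        self._record(
            "pqtl",
            {"alpha": cfg.alpha_pqtl, "cis_window_bp": cfg.cis_window_bp},
            [path, pairs_path],
            {
                "n_pqtl_records": len(records),
                "n_gwas_pqtl_pairs": len(pairs),
                "n_pqtl_proteins": len(proteins),
            },
        )

    def stage_gene_scores(self, skip: bool = False) -> None:
        c = self.state["cohort"]
        path = self.out / "gene_scores.tsv"
        if skip and path.exists():
            self.state["gene_scores"] = io.read_tsv(path)
            return
        scores = genescore.gene_scores_from_sumstats(
            self.state["meta"], c.variant_table, c.gene_annotation,
            genotypes=c.genotypes, flank_bp=self.config.gene_flank_bp,
        )
        self.state["gene_scores"] = scores
        io.write_tsv(scores, path)
        self._record("gene_scores", {"flank_bp": self.config.gene_flank_bp}, [path],
                     {"n_genes": len(scores)})

    def stage_modules(self, skip: bool = False) -> None:
        c = self.state["cohort"]
        cfg = self.config
        G = netmod.build_weighted_ppi(c.ppi_edges, self.state["gene_scores"])
        self.state["ppi"] = G
        path = self.out / "modules.tsv"
        params = netmod.SearchParams(d=cfg.d, r=cfg.r, b_norm=cfg.b_norm)
        if skip and path.exists():
            df = io.read_tsv(path)
            modules = [
                netmod.Module(
                    seed=row["seed"], nodes=frozenset(row["members"].split(";")),
                    zm=row["Zm"], zn=row["Zn"],
                    rank=None if pd.isna(row["rank"]) else int(row["rank"]),
                )
                for _, row in df.iterrows()
            ]
        else:
            modules = netmod.dense_module_search(G, params)
            modules = netmod.normalize_modules(
                modules, G, b_norm=cfg.b_norm, seed=cfg.seed + 7
            )
        top, union = netmod.top_percent_modules(modules, cfg.top_fraction)
        ov, p, odds = netmod.overlap_test(
            self.state["pqtl_proteins"], union, G.number_of_nodes()
        )
        self.state.update(modules=modules, top_modules=top, module_union=union,
                          module_overlap=(ov, p, odds))
        if skip:
            return
        io.write_tsv(netmod.modules_to_frame(modules), path)
        top_path = self.out / "top_modules.tsv"
        io.write_tsv(netmod.modules_to_frame(top), top_path)
        self._record(
            "modules",
            {"d": cfg.d, "r": cfg.r, "top_fraction": cfg.top_fraction,
             "b_norm": cfg.b_norm},
            [path, top_path],
            {"n_modules": len(modules), "n_top": len(top),
             "n_union_proteins": len(union), "overlap_with_pqtl": ov,
             "overlap_p": p},
        )

    def stage_neighbors(self, skip: bool = False) -> None:
        cfg = self.config
        G = self.state["ppi"]
        hits = self.state["gwas_hits"]
        c = self.state["cohort"]
        # map GWAS hit variants to their genes: risk loci on the network
        assignment = genescore.assign_snps_to_genes(
            c.variant_table, c.gene_annotation, flank_bp=cfg.gene_flank_bp
        )
        hit_ids = set(hits["variant_id"])
        risk_loci = {g for g, vids in assignment.items() if hit_ids & set(vids)}
        risk_loci &= set(G.nodes)
        path = self.out / "first_degree.tsv"
        if risk_loci:
            sub = netmod.first_degree_network(G, risk_loci, self.state["pqtl_proteins"])
            neighbors = set(sub.nodes) - risk_loci
            p_emp, p_obs = netmod.permutation_enrichment(
                G, neighbors, self.state["pqtl_proteins"],
                B=cfg.b_perm, seed=cfg.seed + 11,
            )
        else:
            sub, neighbors, p_emp, p_obs = None, set(), float("nan"), float("nan")
        self.state.update(risk_loci=risk_loci, neighbor_set=neighbors,
                          perm_p=p_emp, perm_p_obs=p_obs)
        if skip:
            return
        rows = [
            {"node": v, "risk_locus": v in risk_loci,
             "pqtl_protein": v in self.state["pqtl_proteins"]}
            for v in sorted(sub.nodes)
        ] if sub is not None else []
        io.write_tsv(pd.DataFrame(rows, columns=["node", "risk_locus", "pqtl_protein"]), path)
        self._record(
            "neighbors", {"B": cfg.b_perm}, [path],
            {"n_risk_loci": len(risk_loci), "n_neighbors": len(neighbors),
             "perm_p": p_emp},
        )

    def stage_causal(self, skip: bool = False) -> None:
        cfg = self.config
        c = self.state["cohort"]
        records = self.state["pqtl"]
        meta = self.state["meta"]
        out_stats = meta.rename(
            columns={"beta_meta": "beta", "se_meta": "se", "p_meta": "p"}
        )
        vt = c.variant_table.set_index("variant_id")

        # cis instruments per protein, clumped on the synthetic LD
        instruments: dict[str, pd.DataFrame] = {}
        alpha_inst = cfg.mr_alpha_instruments
        nlp_min = -np.log10(alpha_inst)
        cis = records[(records["cis_flag"] == "cis") & (records["neg_log10_p"] > nlp_min)]
        for protein, sub in cis.groupby("protein"):
            sub = sub.copy()
            sub["p"] = pqtl.neg_log10_to_p(sub["neg_log10_p"].to_numpy())
            idx = [vt.index.get_loc(v) for v in sub["variant_id"]]
            X = c.genotypes[:, idx].astype(float)
            X[X == -1] = np.nan
            X = np.where(np.isnan(X), np.nanmean(X, axis=0), X)
            sd = X.std(axis=0)
            keep = sd > 0
            sub = sub[keep]
            if sub.empty:
                continue
            Rm = np.atleast_2d(np.corrcoef(X[:, keep], rowvar=False))
            R = pd.DataFrame(Rm, index=sub["variant_id"], columns=sub["variant_id"])
            clumped = causal.ld_clump(sub, R, r2_max=cfg.r2_clump)
            exp_df = clumped.assign(
                chrom=[vt.loc[v, "chrom"] for v in clumped["variant_id"]],
                effect_allele=[vt.loc[v, "effect_allele"] for v in clumped["variant_id"]],
                other_allele=[vt.loc[v, "other_allele"] for v in clumped["variant_id"]],
                eaf=[vt.loc[v, "frequency"] for v in clumped["variant_id"]],
            )
            harmonized = causal.harmonize(exp_df, out_stats)
            if not harmonized.empty:
                instruments[protein] = harmonized
        mr = causal.mr_per_protein(instruments, seed=cfg.seed + 13)
        pleio = {
            prot: causal.pleiotropy_global_test(inst, seed=cfg.seed + 17)
            for prot, inst in instruments.items()
        }

        # colocalization + fine-mapping per GWAS-hit region
        coloc_rows, cs_rows = [], []
        hits = self.state["gwas_hits"]
        for _, hit in hits.iterrows():
            chrom, pos = hit["chrom"], hit["pos"]
            region_mask = (out_stats["chrom"].astype(str) == str(chrom)) & (
                np.abs(out_stats["pos"] - pos) <= cfg.finemap_window_bp
            )
            region = out_stats[region_mask]
            if region.empty:
                continue
            cs = causal.finemap_single_causal(
                region, w=causal.W_CC, region=hit["variant_id"]
            )
            for _, r in cs.pips.iterrows():
                cs_rows.append(
                    {"region": hit["variant_id"], "variant_id": r["variant_id"],
                     "pip": r["pip"], "in_cs95": bool(r["in_cs95"])}
                )
            # coloc against each protein with a cis record in the region
            region_v = set(region["variant_id"])
            for protein, sub in records.groupby("protein"):
                if not (set(sub["variant_id"]) & region_v):
                    continue
                prot_stats = self._protein_region_stats(protein, region_v)
                if prot_stats is None or len(prot_stats) < 2:
                    continue
                res = causal.coloc_abf(
                    prot_stats, region.rename(columns={"beta": "beta", "se": "se"}),
                    priors={"p1": cfg.coloc_p1, "p2": cfg.coloc_p2,
                            "p12": cfg.coloc_p12},
                    region=f"{hit['variant_id']}:{protein}",
                )
                row = res.as_dict()
                row["protein"] = protein
                coloc_rows.append(row)

        self.state.update(
            mr=mr, pleiotropy=pleio,
            coloc=pd.DataFrame(coloc_rows),
            credible_sets=pd.DataFrame(cs_rows),
            mr_instruments=instruments,
        )
        if skip:
            return
        mr_path = self.out / "mr_results.tsv"
        coloc_path = self.out / "coloc.tsv"
        cs_path = self.out / "credible_sets.tsv"
        io.write_tsv(mr, mr_path)
        io.write_tsv(self.state["coloc"], coloc_path)
        io.write_tsv(self.state["credible_sets"], cs_path)
        n_sig = int((mr[mr["fdr"].notna()]["fdr"] < cfg.fdr_max).sum()) if len(mr) else 0
        self._record(
            "causal",
            {"r2_clump": cfg.r2_clump, "priors": [cfg.coloc_p1, cfg.coloc_p2,
                                                  cfg.coloc_p12],
             "finemap_window_bp": cfg.finemap_window_bp},
            [mr_path, coloc_path, cs_path],
            {"n_proteins_mr": mr["protein"].nunique() if len(mr) else 0,
             "n_mr_fdr_sig": n_sig, "n_coloc_regions": len(coloc_rows)},
        )

    def _protein_region_stats(self, protein: str, region_variants: set[str]):
        """Full per-variant OLS stats of one protein over a region."""
        c = self.state["cohort"]
        vt = c.variant_table
        mask = vt["variant_id"].isin(region_variants).to_numpy()
        if not mask.any():
            return None
        sub_vt = vt[mask]
        scan = pqtl.pqtl_scan(
            c.proteins[[protein]], c.genotypes[:, mask], c.covariates, sub_vt,
            alpha=1.0,  # keep every variant: coloc needs the full region
        )
        if scan.empty:
            return None
        return scan.rename(columns={"beta": "beta", "se": "se"})[
            ["variant_id", "beta", "se"]
        ]

    def stage_evidence(self, skip: bool = False) -> None:
        cfg = self.config
        c = self.state["cohort"]
        set_a = set(self.state["pqtl_proteins"])
        set_b = self.state["module_union"] & set_a
        set_c = self.state["neighbor_set"] & set_a
        evidence = enrich.triangulate(set_a, set_b, set_c, rule=cfg.triangulation_rule)
        background = list(c.proteins.columns)
        enrichment = enrich.pathway_enrichment(
            set_a, c.gene_sets, background, fdr_max=cfg.fdr_max, min_overlap=1
        )
        hits = self.state["gwas_hits"]
        loop_links = enrich.map_variants_to_loops(
            hits[["variant_id", "chrom", "pos"]], c.loops
        ) if len(hits) else pd.DataFrame(
            columns=["variant_id", "distal_gene", "cell_type"]
        )
        self.state.update(evidence=evidence, enrichment=enrichment,
                          loop_links=loop_links)
        if skip:
            return
        paths = [self.out / "evidence.tsv", self.out / "enrichment.tsv",
                 self.out / "loop_links.tsv"]
        io.write_tsv(evidence, paths[0])
        io.write_tsv(enrichment, paths[1])
        io.write_tsv(loop_links, paths[2])
        n_conv = int(evidence["converging"].sum()) if len(evidence) else 0
        self._record(
            "evidence", {"rule": cfg.triangulation_rule}, paths,
            {"n_converging": n_conv, "n_enriched_sets":
                int(enrichment["significant"].sum()) if len(enrichment) else 0,
             "n_loop_links": len(loop_links)},
        )


def run_pipeline(config: PipelineConfig, force: bool = False) -> PipelineRunner:
    """Execute all stages; returns the runner with state and manifest."""
    runner = PipelineRunner(config, force=force)
    runner.run()
    return runner
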