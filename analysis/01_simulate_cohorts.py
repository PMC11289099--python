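"""Simulate the study inputs: two LD-blocked case/control cohorts with a
shared sparse causal architecture, a 40-protein plasma panel with cis and
trans genetic effects, a scale-free PPI carrying a planted disease module,
gene sets, and chromatin-loop anchors.

Writes variants, genotyped covariates/phenotypes, PPI edges, gene sets,
loops, and the ground-truth pQTL table under results/pipeline_run/.
"""

from common import runner


def main() -> None:
    r = runner()
    r.run(until="simulate")
    cohort = r.state["cohort"]
    spec = cohort.spec
    print(f"cohort A: {spec.n_samples} samples, {spec.n_variants} variants "
          f"in {spec.n_blocks} LD blocks, {int(cohort.phenotype.sum())} cases")
    print(f"cohort B: {int(r.state['pheno_b'].sum())} cases (shared causal variants)")
    print(f"protein panel: {spec.n_proteins} proteins; "
          f"{len(cohort.truth['pqtl_effects'])} true genetic effects")
    print(f"PPI: {len(cohort.ppi_edges)} edges over {spec.n_ppi_nodes} proteins; "
          f"planted module of {len(cohort.planted_module)}")


if __name__ == "__main__":
    main()
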