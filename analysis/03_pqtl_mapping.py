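"""pQTL scan of the protein panel (OLS with the age/age^2/sex interaction
covariate design, p < 5e-8), cis/trans classification (+-1 kb gene
window), intersection of GWAS hits with pQTLs, and the architecture
summary (proteins per pQTL, pQTLs per protein, cis/trans mix).
"""

from common import runner


def main() -> None:
    r = runner()
    r.run(until="pqtl")
    records = r.state["pqtl"]
    pairs = r.state["pqtl_pairs"]
    arch = r.state["architecture"]
    n_cis = int((records["cis_flag"] == "cis").sum())
    print(f"pQTL records at 5e-8: {len(records)} ({n_cis} cis)")
    print(f"GWAS-hit x pQTL association pairs: {len(pairs)} "
          f"over {len(r.state['pqtl_proteins'])} distinct proteins")
    if arch is not None:
        print(f"architecture: {arch.n_cis_only_proteins} cis-only, "
              f"{arch.n_trans_only_proteins} trans-only, "
              f"{arch.n_both_proteins} both; "
              f"{arch.n_trans_only_pqtls} pQTLs trans-only")


if __name__ == "__main__":
    main()
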