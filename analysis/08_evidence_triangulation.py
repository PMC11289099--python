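"""Converging evidence: pathway enrichment of the pQTL-associated
proteins against the measured-panel background, triangulation across
(a) pQTL proteins, (b) top-module pQTL proteins, and (c) first-degree
neighbor pQTL proteins, and variant-to-distal-gene mapping through
chromatin-loop anchors per cell type.
"""

from common import runner


def main() -> None:
    r = runner()
    r.run(until="evidence")
    evidence = r.state["evidence"]
    enrichment = r.state["enrichment"]
    loops = r.state["loop_links"]
    conv = evidence[evidence["converging"]] if len(evidence) else evidence
    print(f"converging proteins: {len(conv)}"
          + (f" ({', '.join(conv['protein'])})" if len(conv) else ""))
    if len(enrichment):
        sig = enrichment[enrichment["significant"]]
        print(f"enriched gene sets at FDR < 0.05: {len(sig)}")
        for _, row in sig.head(3).iterrows():
            print(f"  {row['set']}: overlap {row['overlap']} "
                  f"fdr={row['fdr']:.2e}")
    print(f"variant-to-distal-gene loop links: {len(loops)}")


if __name__ == "__main__":
    main()
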