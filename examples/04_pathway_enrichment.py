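"""Pathway enrichment of two gene sets and the merged dual-disease table.

Scores two overlapping query sets against a small pathway collection with
the hypergeometric upper tail + Benjamini-Hochberg correction, then merges
the two result tables into the exclusive-A / common / exclusive-B partition
used to compare which parts of a pathway each disease covers.
"""

from pleioscan.enrichment import enrich, merge_pathway_tables, merged_to_frame

gmt = {
    "NK cell signaling": {f"NK{i}" for i in range(12)} | {"SHARED1", "SHARED2"},
    "Interleukin signaling": {f"IL{i}" for i in range(15)} | {"SHARED1"},
    "Housekeeping": {f"HK{i}" for i in range(20)},
}

genes_a = {"NK0", "NK1", "NK2", "SHARED1", "SHARED2", "IL0", "IL1"}
genes_b = {"NK0", "SHARED1", "SHARED2", "IL2", "IL3", "IL4", "IL5"}

res_a = enrich(genes_a, gmt, universe_n=200)
res_b = enrich(genes_b, gmt, universe_n=200)
for label, res in (("A", res_a), ("B", res_b)):
    print(f"disease {label}:")
    for r in res:
        print(f"  {r.pathway_id:24s} hits={len(r.genes_hit):2d} "
              f"p_raw={r.p_raw:.2e} p_bh={r.p_bh:.2e}")

merged = merge_pathway_tables(res_a, res_b)
print(merged_to_frame(merged)[
    ["pathway", "n_exclusive_a", "n_common", "n_exclusive_b"]
].to_string(index=False))

# The merged rows partition each pathway's hits: genes only disease A's set
# covers, genes both cover, and genes only B covers - small p_bh with a
# large common column flags pathways plausibly shared by both diseases.
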