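"""Over-representation analysis of a small gene list against synthetic
gene sets: hypergeometric p-values, BH adjustment, enrichment factors,
and kappa-similarity clustering of the retained terms."""

from famseg import EnrichmentConfig, run_ora

# two overlapping cell-cycle-flavoured terms, one unrelated term, and
# background padding so p-values are meaningful
gene_sets = {
    "GO:A_cell_cycle": ("cell cycle", {"CDK1", "CCNB1", "PLK1", "AURKB", "BUB1"}),
    "GO:B_mitosis": ("mitotic division", {"CDK1", "CCNB1", "PLK1", "KIF11"}),
    "GO:C_adhesion": ("cell adhesion", {"CDH1", "CTNNB1", "ITGB1"}),
    "GO:PAD": ("background", {f"PAD{i}" for i in range(80)}),
}

query = ["CDK1", "CCNB1", "PLK1", "CDH1", "CTNNB1", "ITGB1"]
results = run_ora(query, gene_sets, EnrichmentConfig())

print(f"{'term':<18s} {'k/K':>6s} {'p_raw':>10s} {'p_BH':>10s} "
      f"{'EF':>7s} {'kept':>5s} {'cluster':>8s}")
for r in results:
    print(f"{r.term_id:<18s} {r.k:>3d}/{r.K:<3d} {r.p_raw:>10.3g} "
          f"{r.p_adjusted:>10.3g} {r.enrichment_factor:>7.2f} "
          f"{str(r.retained):>5s} {r.cluster_id:>8d}")

print()
print("Retention needs raw p < 0.01, overlap >= 3 and enrichment factor "
      "> 1.5; retained terms sharing genes (membership kappa > 0.3) fall "
      "into the same cluster, unrelated retained terms into their own.")
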