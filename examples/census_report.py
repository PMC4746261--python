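"""Census statistics and TF-vs-CUG correlation on the packaged reference
table of carbohydrate-catabolism TFs in ten bifidobacterial genomes."""

from regulonkit.report_stats import (
    reference_census,
    reference_rows,
    tf_vs_cug_correlation,
)

census = reference_census()
print(census.table)
print()
print(f"grand total: {census.grand_total} TFs")
for family in ("LacI", "ROK", "TetR"):
    print(
        f"{family}: {int(census.family_totals[family])} TFs "
        f"({int(census.family_percent[family])}% of the inventory)"
    )
print(f"fewest TFs: {census.min_genome[0]} ({census.min_genome[1]})")
print(f"most TFs:   {census.max_genome[0]} ({census.max_genome[1]})")

corr = tf_vs_cug_correlation(reference_rows())
print(
    f"total TFs vs carbohydrate-utilization-gene percentage: "
    f"r = {corr.pearson_r:.4f}, r^2 = {corr.r_squared:.4f} "
    f"(~{corr.r_squared_2dp:.2f})"
)
print(
    "Genomes investing more of their gene repertoire in carbohydrate "
    "utilization carry proportionally more sugar-specific regulators."
)
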