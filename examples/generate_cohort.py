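"""Generate a small synthetic genome cohort with planted regulons.

Builds four 150-kb high-GC genomes sharing two orthologous TF groups, each
with five target operons carrying palindromic binding sites, and prints
what was planted.  The truth file lets every later stage be scored.
"""

from regulonkit.synthetic_cohort import CohortConfig, generate_cohort, write_cohort

config = CohortConfig(
    n_genomes=4,
    genome_length=150_000,
    n_tf_groups=2,
    decoy_fraction=0.0,
    seed=7,
)
genomes, tf_table, truth = generate_cohort(config)
write_cohort(genomes, tf_table, truth, "scratch/example_cohort")

rate, core = config.resolved_site_model()
print(f"genomes: {[g.genome_id for g in genomes]}")
print(f"genes per genome: {[len(g.genes) for g in genomes]}")
print(f"site model: {core} conserved columns, substitution rate {rate:.4f}")
for group_id, group in truth.groups.items():
    print(f"{group_id} ({group.family}): consensus {group.consensus}")
print(f"planted sites: {len(truth.sites)}")
print(
    "Each consensus is self-reverse-complementary; N marks the degenerate "
    "spacer between the two half-sites.  Sites sit -200..-50 nt upstream "
    "of their target operons' translation starts."
)
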