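"""Cohort statistics: medians, MADs, outlier thresholds and R² couplings.

Simulates a small cohort of genomes with varying numbers of planted
two-member groups, summarises each, and pools them.  With all groups of
size 2 the synolog count is exactly twice the group count, so the S-vs-G
regression has R² = 1 — the degenerate extreme of the strong count/group
coupling seen in real cohorts.
"""

from synologs import DetectionConfig, cohort_summarize, detect_synologs, summarize_genome
from synologs.simulate import PlantedGroup, SyntheticDesign, generate_genome
from synologs.stats import outlier_threshold

config = DetectionConfig(kmer_prescreen=True)
summaries = []
for i, n_groups in enumerate([1, 2, 2, 3, 4, 6]):
    design = SyntheticDesign(
        n_background=40 + 10 * i,
        length_range=(60, 120),
        planted_groups=tuple(PlantedGroup(size=2) for _ in range(n_groups)),
        rng_seed=100 + i,
        genome_id=f"genome{i}",
        min_dispersed_gap=10,
    )
    records, _ = generate_genome(design)
    groups, _, _ = detect_synologs(records, config)
    summaries.append(summarize_genome(groups, records))

cohort = cohort_summarize(summaries)
m = cohort.metrics["n_groups"]
print(f"groups per genome: median {m.median} MAD {m.mad} "
      f"range [{m.min}, {m.max}]")
print(f"outlier threshold (median + 2*MAD): {m.outlier_threshold} groups")
print(f"R2(synologs, groups) = {cohort.r2_pairs['n_synologs_vs_n_groups']:.3f}"
      "  (exactly 1: every group has two members)")
print(f"genomes with zero synologs: {cohort.zero_synolog_share}%")

# the same operation applied to a published cohort's printed statistics:
print(f"a cohort with median 20.0 and MAD 13.0 groups flags genomes above "
      f"{outlier_threshold(20.0, 13.0):.0f} groups as expanded")
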