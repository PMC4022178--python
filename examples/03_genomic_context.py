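"""Classify detected groups as tandem or dispersed and profile neighbours.

Tandem groups (members adjacent on one contig, at most 2 intervening genes
by default) usually reflect recent local duplication; dispersed members sit
in different genomic contexts, summarised here by the functional categories
of the genes flanking each member.
"""

from synologs import DetectionConfig, call_contexts, detect_synologs
from synologs.simulate import generate_genome, standard_design

design = standard_design(rng_seed=3)
records, truth = generate_genome(design)
groups, _, _ = detect_synologs(records, DetectionConfig(kmer_prescreen=True))

calls = call_contexts(groups, records, max_intervening=2, window=3)
for call in calls:
    top = max(call.neighbor_profile, key=call.neighbor_profile.get) \
        if call.neighbor_profile else "-"
    print(f"{call.group_id}: {call.arrangement:9s} contigs={call.contig_count} "
          f"dominant neighbour category: {top}")

n_tandem = sum(1 for c in calls if c.arrangement == "tandem")
print(f"\n{n_tandem}/{len(calls)} groups tandem; the rest are dispersed "
      "across the chromosome, so their copies sit in different neighbourhoods.")
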