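"""Generate a complete synthetic water-deficit study with ground truth.

Builds the miRNA reference (mature + hairpin), transcripts with planted
binding sites and one target-mimic locus, a read-level small-RNA
library, a degradome tag table, an NB count matrix over the three
watering treatments, and a qPCR Ct table — then prints what was
planted, which is what the downstream examples try to recover.
"""

from rootmir import SimulationConfig, simulate_study

config = SimulationConfig(seed=7, read_depth=20_000)
study = simulate_study(config, outdir="scratch/example_study")

truth = study["truth"]
print(f"miRNA reference: {len(study['reference'])} mature miRNAs "
      f"({len(study['reference'].group_ids)} merged groups)")
print(f"transcripts: {len(study['transcripts'])}")
print(f"small-RNA reads in library WWR1: {len(study['srna_records'])}")
print(f"degradome tag rows: {len(study['degradome_table'])}")
print(f"count matrix: {study['counts'].shape[0]} miRNAs x "
      f"{study['counts'].shape[1]} libraries")
print()
print("planted miRNA binding sites (degradome should validate these):")
print(truth.target_sites.to_string(index=False))
print()
m = truth.mimic
print(f"planted target mimic: {m['transcript_id']}:{m['start']}-{m['end']} "
      f"for {m['mirna_id']} ({m['insert_len']}-nt bulge after position "
      f"{m['bulge_after']})")
n_de = int(truth.true_de.is_de.sum())
print(f"planted differential miRNAs in the count matrix: {n_de}")
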