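"""Degradome target validation and target-mimic detection.

Maps degradome tag 5' ends onto transcripts, finds miRNA binding sites
(< 4 mismatches), and calls a target valid when at least one tag 5'
end lies on a base paired to miRNA positions 9-11 — the slicing
register.  Then scans for target-mimic loci: near-perfect
complementarity interrupted by a small insertion bulge opposite
positions 10-11, which makes the transcript bind the miRNA without
being cleavable.
"""

from rootmir import (
    SimulationConfig,
    call_targets,
    find_sites,
    make_reference,
    mimic_report,
    pileup_from_table,
    scan_mimics,
    simulate_degradome,
    targets_table,
)
from rootmir.mimic_scan import pairing_diagram

config = SimulationConfig(seed=7)
reference, transcripts, truth = make_reference(config)
tag_table, _ = simulate_degradome(
    transcripts, truth, peak_fraction=0.8, noise_rate=0.01, seed=7
)
pileups = pileup_from_table(tag_table, transcripts)

sites = []
for record in reference:
    for tid, seq in transcripts.items():
        sites.extend(find_sites(record.mature_seq, seq, record.mirna_id, tid))
calls = call_targets(sites, pileups)
table = targets_table(calls)
valid = table[table.valid]
print(f"binding sites with < 4 mismatches: {len(table)}; "
      f"degradome-validated targets: {len(valid)}")
print(valid[["mirna_id", "transcript_id", "site_start", "mismatch_count",
             "valid_reads_9_11", "category"]].to_string(index=False))

mid = truth.mimic["mirna_id"]
mature = reference[mid].mature_seq
hits = scan_mimics(transcripts, mature, mid)
print(f"\ntarget-mimic loci for {mid}: {len(hits)}")
for h in hits:
    print(f"  {h.transcript_id}:{h.start}-{h.end}, {len(h.inserted_bases)}-nt "
          f"bulge after miRNA position {h.bulge_after}, "
          f"{h.mismatches_outside_bulge} mismatches outside the bulge")
    print(pairing_diagram(h, mature, transcripts[h.transcript_id]))

report = mimic_report(hits, calls)
print("mimic vs degradome (a real mimic is never cleaved):")
print(report[["transcript_id", "mirna_id", "start", "end",
              "degradome_cleaved"]].to_string(index=False))
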