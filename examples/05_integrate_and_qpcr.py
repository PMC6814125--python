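"""Coherence classes and stem-loop RT-qPCR cross-validation.

Joins miRNA and transcript differential-abundance calls over
degradome-valid pairs into the three coherence classes (target
unchanged / positively correlated / inversely correlated — the last
being the signature of miRNA-guided cleavage), then validates
sequencing fold changes against simulated ddCt qPCR measurements with
a Spearman rank correlation.
"""

import numpy as np
import pandas as pd

from rootmir import (
    SimulationConfig,
    classify_coherence,
    cross_platform_correlation,
    ddct,
    run_de,
    select_reference,
    simulate_counts,
    simulate_qpcr,
)

config = SimulationConfig(seed=11, library_depth=200_000)
counts, groups, truth = simulate_counts(config)
de = run_de(counts, groups, control="WW", treatment="severe")

# coherence: pair each planted DE miRNA with a pretend target transcript
rows = []
for i, mirna in enumerate(truth.index[truth.is_de]):
    t_lfc = float(truth.loc[mirna, "log2_effect_severe"])
    flip = -1.0 if i % 2 else 1.0  # half inverse, half positive pairs
    rows.append({
        "mirna_id": mirna, "transcript_id": f"tx_{mirna}", "contrast": "severe",
        "mirna_log2FC": float(de.loc[mirna, "log2FC"]),
        "mirna_FDR": float(de.loc[mirna, "FDR"]),
        "transcript_log2FC": flip * t_lfc if t_lfc else 0.05,
        "transcript_FDR": 0.01 if t_lfc else 0.8,
    })
table, class_counts = classify_coherence(pd.DataFrame(rows))
print("coherence classes over", len(rows), "miRNA-transcript pairs:")
for cls, n in sorted(class_counts.items()):
    print(f"  {cls}: {n}")

# qPCR panel: planted reference miRNAs normalise the DE panel
ct = simulate_qpcr(truth, pd.Series(1e-3, index=truth.index), seed=11)
decoys = truth.index[truth.log2_effect_severe.abs() >= 2][:2].tolist()
candidates = truth.index[truth.is_reference].tolist() + decoys
refs = select_reference(ct, candidates)
print(f"\nstable reference miRNAs selected from {len(candidates)} candidates "
      f"(the {len(decoys)} stress-responsive decoys are rejected): {refs}")

panel = [p for p in truth.index[truth.log2_effect_severe != 0][:8]
         if p not in refs]
rq = {r.target_id: np.log2(r.rq)
      for r in ddct(ct, refs, "WW") if r.treatment == "severe"}
seq_lfc = [float(de.loc[p, "log2FC"]) for p in panel]
qpcr_lfc = [rq[p] for p in panel]
rho, p = cross_platform_correlation(seq_lfc, qpcr_lfc)
print(f"\nsequencing vs qPCR log2 fold changes over {len(panel)} miRNAs: "
      f"Spearman rho = {rho:.2f}, p = {p:.4f}")
print("(a strong positive rho means the two platforms rank the "
      "water-deficit responses the same way)")
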