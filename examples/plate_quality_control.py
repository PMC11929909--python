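"""Normalize a raw luminescence plate and gate it on assay quality."""

import qpop

design = qpop.build_oacd(12)
truth = qpop.gen_ground_truth(12, noise_sd=0.02, seed=5)
plate = qpop.simulate_plate(truth, design, seed=6)

viab = qpop.normalize(plate)
print(
    f"normalized {len(viab.replicates)} treatment wells into "
    f"{len(viab.summary)} runs; {viab.n_flagged} NCVs flagged outside [-0.2, 1.5]"
)
print(viab.summary.head(3).to_string(index=False))

pos = plate.control_values("pos_ctrl")
neg = plate.control_values("neg_ctrl")
z = qpop.zprime(pos, neg)
s = qpop.ssmd(pos, neg)
print(f"\nZ' = {z:.3f}, SSMD = {s:.1f}")
print(
    "Z' >= 0.5 marks an excellent assay window (control separation large "
    "relative to control noise); this plate "
    + ("passes" if z >= 0.5 else "fails")
    + " the default gate."
)
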