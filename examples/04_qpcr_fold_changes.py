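"""Relative qPCR quantification with the comparative-CT (2^-ddCT) method.

Simulates a noiseless CT table for one target gene across four samples with
true relative expression 1:2:4:8 against an H2afz reference, then recovers
the fold changes.  The lowest-expressed sample is the calibrator (fold 1).
"""

from u12retain import delta_delta_ct, simulate_ct_table

table = simulate_ct_table({"Zrsr1": [1, 2, 4, 8]}, noise_sd=0.0, seed=7)
result = delta_delta_ct(table, target_gene="Zrsr1", reference_gene="H2afz")
print(result.round(3).to_string(index=False))
# delta_ct drops by one cycle per doubling; fold_change recovers 1, 2, 4, 8
# exactly because no CT noise was simulated.
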