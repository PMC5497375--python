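"""qPCR relative expression (ddCt) and centrosome-abnormality statistics.

ddCt: fold change = 2^-(dCt_sample - dCt_calibrator) with dCt = Ct_target -
Ct_housekeeping.  Centrosomes: per-dose chi-square tests of the proportion
of cells with more than two centrosomes against the untreated control.
"""

import pivotnet as pn

# --- ddCt ------------------------------------------------------------------
# treated sample: target Ct 24.0, housekeeping (18S) Ct 12.0
# untreated calibrator: target Ct 25.5, housekeeping Ct 12.2
fc = pn.ddct_relative_expression(24.0, 12.0, 25.5, 12.2)
print(f"ddCt fold change vs untreated control: {fc:.2f}")
print("(> 1 means the gene is upregulated in the treated sample)")

# --- centrosome counts -----------------------------------------------------
counts = pn.generate_centrosome_counts(
    conditions=["CTR", "4uM", "8uM", "16uM", "32uM", "64uM"],
    true_proportions=[0.01, 0.01, 0.02, 0.03, 0.05, 0.12],
    n_range=(250, 270), seed=4)
print()
print(counts.to_string(index=False))
summary = pn.dose_response_table(counts, "CTR")
print()
print(summary.table.to_string(index=False))
print()
print("abnormal proportion non-decreasing with dose:",
      summary.proportions_nondecreasing)
print("Stars mark doses whose proportion of cells with >2 centrosomes "
      "differs significantly from control (chi-square, p <= 0.05).")
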