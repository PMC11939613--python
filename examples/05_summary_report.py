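"""Cross-drug summary: join calcium suppression with cytotoxicity.

Builds the summary table for a small simulated screen - five drugs with
matched calcium-imaging and viability results, one with a missing
viability assay - and quantifies the association between residual calcium
activity at 40 min and maximum cell-kill.
"""

from cawave import report

calcium = [
    ("BLOCK-A", "cell-line", 0.0, 50.0),
    ("BLOCK-B", "cell-line", 10.0, 50.0),
    ("PUMP-A", "cell-line", 5.0, 10.0),
    ("WEAK-A", "cell-line", 35.0, 20.0),
    ("WEAK-B", "cell-line", 30.0, 100.0),
]
kills = [
    ("BLOCK-A", "cell-line", 97.0, 50.0),
    ("BLOCK-B", "cell-line", 85.0, 50.0),
    ("PUMP-A", "cell-line", 95.0, 10.0),
    ("WEAK-A", "cell-line", 31.0, 20.0),
    # WEAK-B viability deliberately not run
]

rows = report.build_summary_table(calcium, kills)
print(report.summary_to_frame(rows).to_string(index=False))
print()
print(report.association_report(rows))
print()
print("Drugs that abolish calcium activity cluster with high kill; the")
print("negative Spearman coefficient quantifies that inverse relationship.")
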