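"""Recompute the published diagnostic rates from their printed counts.

The development study printed TP/TN/FP/FN counts for the 4-item model
(and each single item) at two USG cut-offs and two assessment times.
Feeding those counts through the package's rate arithmetic reproduces
every printed sensitivity and specificity to one decimal.
"""

from hydrascore import ContingencyTable, sens_spec_acc
from hydrascore.validation_counts import PUBLISHED_ROWS

print(f"{'session':9s} {'cutoff':6s} {'variable':9s}  "
      f"{'sens%':>6s} {'spec%':>6s}  printed")
mismatches = 0
for row in PUBLISHED_ROWS:
    rates = sens_spec_acc(ContingencyTable(tp=row.tp, tn=row.tn, fp=row.fp, fn=row.fn))
    ok = (rates["sensitivity"] == row.sensitivity_pct
          and rates["specificity"] == row.specificity_pct)
    mismatches += not ok
    print(f"{row.session:9s} {row.cutoff:6s} {row.variable:9s}  "
          f"{rates['sensitivity']:6.1f} {rates['specificity']:6.1f}  "
          f"{row.sensitivity_pct:.1f}/{row.specificity_pct:.1f} "
          f"{'ok' if ok else 'MISMATCH'}")
print(f"\n{len(PUBLISHED_ROWS)} rows checked, {mismatches} mismatches")
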