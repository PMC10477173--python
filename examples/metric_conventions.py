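"""Evaluate the confusion-count metric formulas under both reporting
conventions on a worked example.

The published formula set conflicts with its own symbol glossary (it prints
specificity with the false-positive count in the numerator, accuracy as
(B+D)/total, precision as A/(A+C), and identical TPR/FPR right-hand sides).
Both readings are implemented: `standard` uses the textbook definitions and
is the default; `paper_literal` evaluates the formulas exactly as printed so
the divergence is auditable.
"""

from meningiodet import ConfusionCounts, compute_metrics

counts = ConfusionCounts(A=45, B=5, C=5, D=45)  # 100 pixels, 10 errors
print(f"counts: TN={counts.A} FP={counts.B} FN={counts.C} TP={counts.D}\n")

for convention in ("standard", "paper_literal"):
    report = compute_metrics(counts, convention)
    print(f"[{convention}]")
    for name, value in report.as_dict().items():
        if name == "convention":
            continue
        print(f"  {name:>13}: {value if value is not None else 'undefined'}")
    print()

print(
    "note how segmentation accuracy is 90% under the standard reading but\n"
    "50% under the printed formula (B+D)/total — the literal numerator\n"
    "counts false positives as successes."
)
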