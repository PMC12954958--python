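"""Validation statistics from a field-trial tally.

Feeds the per-status ground-truth / assessed / correct counts of a two-plot
field trial (594 theoretical points) into the reporting module and prints
the accuracy table, the Wilson 95 % confidence interval for the overall
accuracy, and one-sided significance tests against an 85 % baseline.
"""

from transplantqc import (
    StatusSummary,
    TransplantStatus,
    abnormality_rate,
    accuracy_tests,
    summary_accuracy,
)

counts = {
    TransplantStatus.NORMAL: (503, 495, 463),
    TransplantStatus.ROOT_EXPOSURE: (16, 13, 13),
    TransplantStatus.SEEDLING_BURIAL: (13, 14, 10),
    TransplantStatus.MISSED_PLANTING: (51, 57, 45),
    TransplantStatus.DOUBLE_PLANTING: (11, 10, 8),
}
summary = StatusSummary.from_counts(counts)
for status, acc in summary_accuracy(summary).items():
    print(f"{status:>16}: {acc} %")

total = summary.total
inf = accuracy_tests(total.correct, total.ground_truth, p0=0.85)
print(f"\noverall {total.correct}/{total.ground_truth} correct")
print(f"Wilson 95% CI: [{inf.wilson_low} %, {inf.wilson_high} %]")
print(f"one-sided z test vs 85%:        p = {inf.p_z:.3g}")
print(f"one-sided binomial test vs 85%: p = {inf.p_binom:.3g}")
print(f"abnormality rate: {abnormality_rate(summary):.2f} %")
# Both p-values ≪ 0.05: the observed accuracy significantly exceeds the
# 85 % baseline; the Wilson interval brackets the plausible true accuracy.
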