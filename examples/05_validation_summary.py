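"""Summarize expert validation counts for expanded verb classes.

Loads the packaged 14-class expert-judgement table (7 general-scientific
and 7 biomedical classes) and computes per-class percentages plus macro
(unweighted mean of class percentages) and micro (pooled counts) totals.
"""

from bioverb import expert_validation_records, summarize
from bioverb.validation import round_half_up

records = expert_validation_records()
summary = summarize(records)

print(f"{'class':26s} {'domain':11s} {'n':>3s} {'correct':>7s} {'% corr':>7s}")
for r in summary.per_class:
    print(
        f"{r.class_index + ' ' + r.class_name:26s} {r.domain:11s} "
        f"{r.n_candidates:3d} {r.n_correct:7d} {round_half_up(r.pct_correct):7.1f}"
    )

for key in ("general", "biomedical", "overall"):
    t = summary.totals[key]
    print(
        f"\n{key}: {t.sum_candidates} candidates, {t.sum_correct} correct; "
        f"macro {round_half_up(t.macro_pct_incorrect)}% incorrect "
        f"(micro {round_half_up(t.micro_pct_incorrect)}%)"
    )
print(
    "\nMacro totals average the class percentages and so weight small and"
    "\nlarge classes equally; micro totals pool the raw counts."
)
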