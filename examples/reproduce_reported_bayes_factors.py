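"""Recompute the published Bayes factors from the printed group summaries.

No raw EEG is needed: each load effect's standard error is recovered from
its printed 95% CI via the t(0.975, 48) quantile, and the uniform-prior
([-1.5, +1.5] uV, t likelihood) and flat-prior correlation BFs are then
recomputed exactly as the evidence layer defines them.
"""

from mmnload import reproduce_printed_bfs

table = reproduce_printed_bfs()
cols = ["measure", "effect_mean", "bf01_two_sided", "bf10_two_sided",
        "bf01_directional", "label_two_sided"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.2f}"))

print(
    "\nbf01 > 1 favors no load effect. The oddball-MMN row (BF01 ~ 3.6 "
    "two-tailed, ~5.4 one-tailed) is moderate evidence that visual load "
    "leaves the MMN unchanged, while the visual-P3 row (BF10 > 200) is "
    "extreme evidence that the load manipulation itself worked."
)
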