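"""Recover recurrent local expression patterns from a noisy synthetic field.

Plants three contiguous spatial patterns, each carried by 10 genes at 2-3
time points, adds 5% cell-flip noise, jitter and missing cells, then runs
demarcation, global-state calling, component pooling and overlap
clustering, and scores the recovered patterns against the planted truth.
"""

from gridpatterns import (
    default_config,
    generate_field,
    pattern_recovery_jaccards,
    run_pipeline,
    state_recovery_rate,
)

cfg = default_config(seed=1, flip_rate=0.05)
field, truth = generate_field(cfg)
res = run_pipeline(field)

print(f"quantized slices: {len(res.quantized)}  pooled components: {len(res.pool)}")
print(f"state-vector recovery: {100 * state_recovery_rate(truth, res.vectors):.0f}%")

prominent = [cl for cl in res.clusters if cl.occurrence_count >= 5]
print(f"\nprominent recurrent patterns (>= 5 member occurrences): {len(prominent)}")
for i, cl in enumerate(prominent, 1):
    fm = cl.frequency_map()
    core = sorted((c.ap, c.dv) for c, f in fm.items() if f >= 0.5)
    print(
        f"  pattern {i}: {cl.occurrence_count} occurrences in"
        f" {cl.gene_count} genes, core cells {core}"
    )

jaccards = pattern_recovery_jaccards(truth, res.clusters)
print("\nmembership Jaccard vs planted patterns:", [round(j, 3) for j in jaccards])
print(
    "Each planted pattern is recovered as one cluster whose (gene, time)"
    " members\noverlap the planted occurrences at Jaccard >= 0.8 despite"
    " the noise."
)
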