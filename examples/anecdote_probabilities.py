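"""How misleading would a single simulation per condition be?

Given transition tallies from repeated simulations in three box sizes,
enumerate the probability of every qualitative conclusion ("a transition
occurs in box b") an N = 1 study could have reached.
"""

import mdinfer as m

counts = m.BoxOutcomeCounts({"9nm": (12, 21), "12nm": (5, 11), "15nm": (9, 21)})

for pooled, label in [(False, "per-box frequencies"), (True, "pooled frequency")]:
    probs = m.conclusion_probabilities(counts, pooled=pooled)
    print(f"\n{label}:")
    for pattern, p in sorted(probs.items(), key=lambda kv: -kv[1]):
        name = ", ".join(
            b for b, hit in zip(counts.labels, pattern) if hit
        ) or "none"
        print(f"  transition in [{name:>16s}]: {p:.3f}")

# Every pattern has appreciable probability: with one trajectory per box,
# most runs of the 'experiment' would support some spurious box-size
# story purely by chance.
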