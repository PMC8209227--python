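"""Derive a positivity threshold from negative controls and call samples.

The limit of detection is the upper bound of a strict (99.98%)
t-distribution confidence interval on the mean VAF of negative
controls; any sample strictly above it is called mutation-positive.
"""

import ddrain

# Measured VAFs of wild-type (negative-control) reactions: background
# mutant signal from misclassification and chemistry noise.
control_vafs = [3.1, 4.0, 2.6, 3.4, 3.8]

thr = ddrain.positivity_threshold(control_vafs, confidence=0.9998)
print(
    f"threshold = {thr.threshold_percent:.2f}% "
    f"({thr.confidence:.2%} CI upper bound, n={thr.n_controls} controls)"
)

for vaf in [0.5, thr.threshold_percent, 9.9, 35.0]:
    print(f"  VAF {vaf:6.2f}% -> {ddrain.call_sample(vaf, thr)}")
# A value exactly at the threshold is negative (the rule is strictly
# 'above'); an undefined VAF would give 'no-call'.
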