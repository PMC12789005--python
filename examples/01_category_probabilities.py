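"""Cell probabilities of the ordered-probit model, with a DK channel.

Builds a 5-category latent-normal model (mean 3 = the neutral midpoint,
sd 1, default thresholds) and prints the probability of each answer
option, then mixes in a 15% "I don't know" probability.
"""

import numpy as np

import ordsurvey as osv

params = osv.OrdinalParams(mu=3.0, sigma=1.0, thresholds=osv.default_thresholds(5))
p = osv.category_probabilities(params)
labels = ["strongly oppose", "oppose", "neutral", "support", "strongly support"]

print("ordinal answer probabilities (mu=3, sigma=1):")
for lab, prob in zip(labels, p):
    print(f"  {lab:>16}: {prob:.4f}  ({osv.display_percent(prob)}%)")
print(f"  sum = {p.sum():.12f}")

adj = osv.dk_adjusted_probabilities(0.15, p)
print("\nwith a 15% 'I don't know' mixture:")
for lab, prob in zip(["don't know"] + labels, adj):
    print(f"  {lab:>16}: {prob:.4f}")

# A respondent's latent opinion z ~ N(3, 1) falls in the 'neutral' bin
# (2.5, 3.5] with probability Phi(0.5) - Phi(-0.5) ~ 0.383; the DK mixture
# rescales every ordinal cell by 0.85 and gives DK the remaining 0.15.
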