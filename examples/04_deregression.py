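"""Deregress an EBV, removing the parent-average contribution.

The 2x2 back-solved system isolates the individual's own information so
that marker models are not trained on redundant family means.
"""

from treegs import deregress

# one individual: heritability 0.25 (lambda = 3), parent average 10,
# EBV 15, parent reliabilities 0.49 each, own reliability 0.55
rec = deregress(pa=10.0, ebv=15.0, r2_pa=0.245, r2_i=0.55, h2=0.25)

print(f"lambda (1-h2)/h2:        {rec.lam:.4f}")
print(f"alpha:                   {rec.alpha:.4f}")
print(f"delta:                   {rec.delta:.5f}")
print(f"PA information content:  {rec.info_pa:.4f}")
print(f"own information content: {rec.info_i:.4f}")
print(f"DEBV:                    {rec.debv:.2f}")

# The deregressed value (25.18) is well above the EBV (15): the individual
# beat its parent average, and removing the shrinkage toward the family
# mean re-expands its own contribution.
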