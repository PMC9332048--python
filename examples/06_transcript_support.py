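"""Two-proportion U test: are predicted promoters transcriptome-supported
more often than random positions?

m1 of n1 predicted-promoter downstream regions had transcript hits versus
m2 of n2 random positions; U compares the two rates with pooled variance.
"""

from ppscan import decide, u_statistic

m1, n1, m2, n2 = 31, 1000, 17, 1000
u = u_statistic((m1, n1, m2, n2))
result = decide(u, alpha=0.05)
print(f"support rates: {m1/n1:.3f} (predictions) vs {m2/n2:.3f} (random)")
print(f"U = {u:.4f}, critical = {result['critical']:.2f} at alpha = 0.05 "
      f"-> {result['decision']}")
# |U| > 1.96 rejects equal support rates: the predicted promoters are
# followed by transcribed sequence significantly more often than chance.
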