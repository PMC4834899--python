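"""One-locus variance decomposition under partial imprinting.

For a locus whose maternal copy is expressed at level rho (0 = fully
silenced, 1 = fully expressed), the genetic variance under Hardy-Weinberg
equilibrium is (1 + rho^2) p q alpha^2 and the part attributable to the
parent-of-origin effect is p q alpha^2 (1 - rho)^2 / 2.  Their ratio -- the
fraction of locus variance a purely additive model cannot represent --
shrinks as imprinting weakens.
"""

from poegp import locus_genetic_variance, locus_poe_variance

p, theta1, theta2 = 0.3, 0.8, -0.4
print(f"allele frequency p = {p}, allele effects {theta1} / {theta2}")
print(f"{'rho':>5} {'genetic var':>12} {'POE var':>9} {'POE share':>10}")
for rho in (0.0, 0.25, 0.5, 0.75, 1.0):
    vg = locus_genetic_variance(p, theta1, theta2, rho)
    vo = locus_poe_variance(p, theta1, theta2, rho)
    share = vo / vg if vg > 0 else float("nan")
    print(f"{rho:5.2f} {vg:12.4f} {vo:9.4f} {share:10.3f}")
print("\nAt rho = 1 the locus is a textbook additive locus (variance "
      "2 p q alpha^2) and the parent-of-origin variance vanishes.")
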