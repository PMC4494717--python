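"""Inter-rater agreement from the study's published severity marginals.

The attending clinician graded 106 infants (76 mild / 27 moderate /
3 severe / 0 normal); the pediatric sonographer's LUS grades were
68 / 26 / 3 / 9 with 96 infants graded identically. Cohen's kappa
corrects the raw agreement for chance.
"""

from luscore import cohen_kappa, expected_agreement, kappa_se0, kappa_z_test

rows = (76, 27, 3, 0)   # clinician: mild, moderate, severe, normal
cols = (68, 26, 3, 9)   # pediatric sonographer
n, diagonal = 106, 96

po = diagonal / n
pe = expected_agreement(rows, cols, n)
kappa = cohen_kappa(po, pe)
se0 = kappa_se0(rows, cols, n)
z, p = kappa_z_test(kappa, se0)

print(f"observed agreement  Po = {100 * po:.1f}%")
print(f"expected agreement  Pe = {100 * pe:.1f}%")
print(f"Cohen's kappa        K = {kappa:.2f}")
print(f"H0 standard error      = {se0:.4f}")
print(f"z = {z:.2f}, one-sided p = {p:.2e}")
# kappa of 0.8 is "excellent" agreement: the raters agree on 90.6% of
# infants where chance alone would give 52.3%.
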