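"""Diagnostic accuracy of the oxygen-need rule on the study's 2x2 table.

Of 106 infants, 29 required supplementary oxygen. The rule "LUS total > 3"
flagged 28 of them (one false negative) and cleared 76 of the 77 others
(one false positive).
"""

from luscore import TwoByTwo, accuracy_panel

table = TwoByTwo(tp=28, fp=1, fn=1, tn=76)

for method in ("wilson", "clopper_pearson"):
    print(f"--- {method} 95% intervals ---")
    for name, est in accuracy_panel(table, ci_method=method).items():
        print(
            f"{name:12s} {100 * est.point:5.1f}%  "
            f"({100 * est.ci_low:.1f}% to {100 * est.ci_high:.1f}%)  "
            f"[{est.numerator}/{est.denominator}]"
        )
# Sensitivity 96.6% and specificity 98.7%: a LUS total above 3 almost
# perfectly separates infants who will need oxygen from those who will not.
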