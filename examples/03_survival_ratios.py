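"""Breeding-ratio tests for the heterozygous-female x transgenic-male cross.

The observed weaning counts are 50 heterozygous females, 88 wild-type
females and 81 males (not genotyped).  With full viability the two female
classes would be 1:1; if all males survived, males vs wild-type females
would be 2:1; with hemizygous mutant males dying before birth it is 1:1.
"""

import mosaicstripes as ms

res = ms.run_survival_test([50, 88, 81])

t = res.het_vs_wt_females_1to1
print(f"het vs WT females, 1:1 : chi2 = {t.chi2:.2f}, P = {t.p_value:.4f}")
t = res.males_vs_wt_females_2to1
print(f"males vs WT females, 2:1: chi2 = {t.chi2:.2f}, P = {t.p_value:.2g}")
t = res.males_vs_wt_females_1to1
print(f"males vs WT females, 1:1: chi2 = {t.chi2:.3f}, P = {t.p_value:.3f}")
print(f"heterozygote deficiency : {res.het_deficiency_percent:.0f}%")
print()
print("The significant 1:1 departure and the 2:1 -> 1:1 pattern in males are")
print("what partial heterozygote lethality plus complete hemizygote lethality")
print("predict for an X-linked loss-of-function mutation.")
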