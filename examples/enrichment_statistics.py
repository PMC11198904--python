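"""The statistical kernel on cohort-scale printed inputs.

These are the self-contained quantities a 1,217-sample breast-cancer
cohort analysis reports: Bonferroni-critical correlation thresholds, a
hypergeometric RNA-chromatin enrichment, a proportion ratio with Fisher
companion, and an extreme binomial tail kept finite in log space.
"""

from lncreg import stats as ls

raw, r = ls.bonferroni_pcc_threshold(1217, 13_963 * 1_079, alpha=0.05)
print(f"critical |r| for ~15M lncRNA-mRNA tests at n=1217: {r} ({raw:.4f})")

hg = ls.hypergeom_tail(318_849, 27_757, 111, 29)
print(f"RNA-chromatin support enrichment: p = {hg.p_value:.6e}")

ratio, fisher_p = ls.proportion_ratio(271, 388, 745, 1079)
print(f"enhancer-overlap proportion ratio: {ratio:.2f} (Fisher p {fisher_p:.2f})")

bt = ls.binomial_tail(699, 11_531, 0.01)
print(f"regulated fraction vs 1% chance: log10 p = {bt.log10_p:.1f}")
# A tail near 1e-302 underflows naive summation; the log-gamma
# accumulation keeps it representable and reports log10 p alongside.
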