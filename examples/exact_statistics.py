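"""The exact statistics layer on published win counts.

The one-sided Fisher exact test and the win ratio can be recomputed directly
from a printed contingency table, without running any simulation.  The table
below is the classic example: 417 of 500 ERS wins against 225 of 500 CRS
wins.
"""

from humoralsim import ContingencyTable, fisher_one_sided, welch_t_test

tbl = ContingencyTable(ers_wins=417, crs_wins=225, ers_losses=83, crs_losses=275)
p = fisher_one_sided(tbl)
ratio = tbl.ers_wins / tbl.crs_wins

print(f"table: wins {tbl.ers_wins} vs {tbl.crs_wins}, "
      f"losses {tbl.ers_losses} vs {tbl.crs_losses}")
print(f"win ratio:           {ratio:.3f}")
print(f"one-sided Fisher p:  {p:.3e}")

p2 = fisher_one_sided(ContingencyTable(208, 66, 292, 434))
print(f"second arm (208 vs 66 wins): ratio {208/66:.3f}, p = {p2:.3e}")

print()
print("Reading: the p-values are upper hypergeometric tails computed in log")
print("space (no underflow even at 1000 runs); a ratio of 1.853 with p≈4.5e-38")
print("means the ERS advantage is overwhelming at this sample size.")
print()
print("The Welch t-test used for elimination-time means is also exposed:")
print("identical samples give p =", welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
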