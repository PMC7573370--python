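"""Rank three lettuce varieties by their dynamic traits (Friedman test).

Blocks are the GR-/AC- columns of the bundled dynamic-trait tables;
treatments are the varieties L1048, L454 and N648.  Ranking is ascending
(rank 1 = smallest) with average ranks for ties, and the chi-square
statistic carries the tie correction C = 1 − Σ(t³−t)/(n(k³−k)).
"""

from phenopot.datasets import lettuce_dynamic_traits
from phenopot.stats import friedman_test, pooled_rank_report

geometric, color = lettuce_dynamic_traits()

for name, table in (("geometric", geometric), ("color", color)):
    res = friedman_test(table.T)          # blocks × varieties
    ranks = ", ".join(f"{t}={r:.2f}"
                      for t, r in zip(res.treatments, res.mean_ranks))
    print(f"{name:>9} traits (n={res.n_blocks} blocks): mean ranks {ranks}")
    print(f"          chi2 = {res.chi2:.3f} (uncorrected "
          f"{res.chi2_uncorrected:.3f}), df={res.df}, p = {res.pvalue:.3f}")

print("\nColor separates these varieties more strongly than geometry "
      "(larger chi-square, smaller p).")

pooled = pooled_rank_report([geometric, color]).sort_values()
print("\nMost / least variety-discriminating dynamic traits "
      "(pooled mean rank of all 30 columns within each variety):")
print(pooled.tail(3).round(1).to_string())
print(pooled.head(3).round(1).to_string())
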