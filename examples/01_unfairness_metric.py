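"""The weekly unfairness statistic for one specialty.

A specialty's weekly unfairness is the mean absolute deviation of each
navigator's workload from the fair (equal) share of the week's total.
"""

from navfair import fair_share, summarize_series, unfairness

loads = [2, 4]
print(f"loads {loads}: fair share = {fair_share(loads):.1f}, "
      f"unfairness = {unfairness(loads):.1f}")
# One navigator carries 1 encounter more, the other 1 less, than the fair 3.

loads = [0, 0, 6]
print(f"loads {loads}: fair share = {fair_share(loads):.2f}, "
      f"unfairness = {unfairness(loads):.4f}")
# All the work sits with one of three navigators: unfairness 8/3.

weekly = [0.8, 0.5, 1.1, 0.2, 0.9, 0.6, 0.4, 0.7]
s = summarize_series(weekly)
print(f"8-week series: mean {s.mean:.3f}, SD {s.sd:.3f}, "
      f"95% CI [{s.ci_low:.3f}, {s.ci_high:.3f}]")
# The CI uses the 1.98 * SD/sqrt(n) half-width convention used throughout.
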