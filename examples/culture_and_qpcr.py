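"""Track population doublings in culture and quantify qPCR fold changes.

PD = log10(N/N0) x 3.33 counts cell doublings per passage (3.33 = 1/log10 2
to two decimals); qPCR relative expression is 2^(-ddCt) against a
housekeeping reference.
"""

from solodiff import cumulative_population_doublings, ddct_fold_change, population_doubling

passages = [(1e5, 4.1e5), (1e5, 3.2e5), (1e5, 1.9e5), (1e5, 1.2e5)]
print("serial passages (cells plated -> harvested):")
cum = cumulative_population_doublings(passages)
for (n0, n), total in zip(passages, cum):
    pd_here = population_doubling(n0, n)
    print(f"  {n0:.0f} -> {n:.0f}: {pd_here:.2f} doublings (cumulative {total:.2f})")
print("slowing growth per passage is the hallmark of approaching senescence\n")

fold = ddct_fold_change(
    ct_target_test=[21.1, 21.3, 21.2],   # target gene, treated sample (triplicate)
    ct_ref_test=[18.0, 18.1, 17.9],      # housekeeping gene, treated
    ct_target_ctrl=[23.0, 22.8, 23.1],   # target gene, control
    ct_ref_ctrl=[18.1, 18.0, 18.2],
)
print(f"qPCR relative expression (2^-ddCt): {fold:.2f}-fold "
      "- the treated sample expresses the target ~3-4x the control")
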