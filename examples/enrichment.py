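"""Biological-system overrepresentation of food-affected drug targets.

Applies the expectation formula exp = (tpc / tdt) * tpa — tpc drug
targets in a biological category, tdt total drug targets (1,806 in the
published totals), tpa drug targets participating in food interactions
(186) — and flags categories whose observed/expected ratio is outlying.
"""

from dfi.networks import EnrichmentInput, category_enrichment

TDT, TPA = 1806, 186
categories = {
    # category: (tpc, observed among the food-affected targets)
    "signal_transduction": (500, 80),
    "immune_system": (250, 40),
    "metabolism": (400, 35),
    "developmental": (156, 21),
    "transport": (300, 7),
    "other": (200, 3),
}

inputs = [EnrichmentInput(c, tpc, TDT, TPA) for c, (tpc, _) in categories.items()]
observed = {c: obs for c, (_, obs) in categories.items()}

print(f"{'category':<22} {'tpc':>5} {'expected':>9} {'observed':>9} {'ratio':>6}  flags")
for r in category_enrichment(inputs, observed):
    flags = []
    if r.t_significant:
        flags.append("t")
    if r.binomial_p < 0.05:
        flags.append(f"binom p={r.binomial_p:.1e}")
    print(f"{r.category:<22} {categories[r.category][0]:>5} {r.expected:>9.2f} "
          f"{r.observed:>9} {r.ratio:>6.2f}  {', '.join(flags) or '-'}")

# 'expected' is the count each category would contribute if food-affected
# targets were drawn uniformly from all drug targets; ratios well above 1
# (flagged) mark systems that phytochemicals preferentially hit.
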