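"""Herb-level drug-property statistics.

Contrasts the 24-bit property profiles of hepatoprotective vs
non-hepatoprotective herbs (chi-squared), then mines association rules with
the consequent fixed to hepatoprotection.
"""

import herbscreen as hs

spec = hs.SyntheticSpec(seed=0, n_herbs=255, n_candidates=0, n_hepato_like=0,
                        n_enriched=0, n_enriched_hepato_like=0)
herbs = hs.generate_herbs(spec)
hep = [h for h in herbs if h.status == hs.HEPATOPROTECTIVE]
non = [h for h in herbs if h.status == hs.NON_HEPATOPROTECTIVE]
print(f"reference herbs: {len(hep)} hepatoprotective / {len(non)} non-hepatoprotective")

A = hs.encode_property_matrix(hep).to_numpy()
B = hs.encode_property_matrix(non).to_numpy()
res = hs.chi_squared_contrast(A, B, mode="omnibus")
print(f"omnibus chi-squared: statistic={res.statistic:.1f} df={res.df} p={res.p:.3g}")

rules = hs.mine_association_rules(herbs, min_support=0.05, min_confidence=0.65,
                                  min_lift=1.0)
prior = len(hep) / (len(hep) + len(non))
print(f"\nrules (consequent = hepatoprotection, prior {prior:.3f}):")
print(f"{'antecedent':<35} {'supp%':>7} {'conf%':>7} {'lift':>6}")
for r in rules[:8]:
    print(f"{r.id_str:<35} {100 * r.support:7.2f} {100 * r.confidence:7.2f} "
          f"{r.lift:6.2f}")

# Lift is confidence over the hepatoprotective prior: a lift of 1.5 means
# herbs with that property combination are 1.5x likelier than average to be
# hepatoprotective.  The planted sour rule targets confidence 0.714.
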