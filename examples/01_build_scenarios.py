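"""Build the six plant-based replacement scenarios from the baseline diet.

Loads the packaged canonical scenario table's baseline (g/person/day per
food group), applies the rule-based substitution engine under the mass
functional unit, and prints the resulting group amounts for a few
scenarios. The flexitarian rule halves every animal-source group; the vegan
rules zero them and move the removed grams into plant-based alternatives
(PBA variant) or whole foods under per-group caps (WHOLE variant).
"""

import dietshift as ds

bau = ds.canonical_bau()
specs = {s.name: s for s in ds.builtin_scenarios("mass")}

print(f"{'group':<22}{'BAU':>8}{'FLXPBA':>8}{'VGNPBA':>8}{'VGNWHOLE':>9}")
flx = ds.substitute(bau, specs["FLXPBA"])
vgn = ds.substitute(bau, specs["VGNPBA"])
vgnw = ds.substitute(bau, specs["VGNWHOLE"])
for group in ds.GROUPS:
    print(
        f"{group:<22}{bau.amount(group):>8.0f}{flx.amount(group):>8.0f}"
        f"{vgn.amount(group):>8.0f}{vgnw.amount(group):>9.0f}"
    )
print(
    f"\ntotal grams conserved (FLXPBA): {flx.total_g:.0f} vs BAU {bau.total_g:.0f}"
    "\nEach column is one diet in g/person/day; replacements conserve mass"
    " except where whole-food caps (e.g. legumes) redirect the overflow."
)
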