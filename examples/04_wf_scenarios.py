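"""Forward Wright-Fisher drift and selection scenarios for two real variants.

LCT scenario: can 500 generations of pure drift at Ne = 2,471 fix the
ancestral (lactose-intolerance) allele when the derived allele starts at the
regional average of 29%?  ACTN3 scenario: can drift alone carry the derived
stop-gain allele from the regional 47% to the isolate's observed 93%, or is
selection (s = 0.01) required?
"""

import isodrift as iso

lct = iso.scenario_lct(seed=13, n_replicates=1000)
print("LCT, neutral drift (Ne=2471, derived p0=0.29, 500 generations):")
print(f"  ancestral allele fixed in {lct.summary['percent_ancestral_fixed']:.1f}% "
      "of 1,000 replicates")
print("  => drift alone almost never fixes the ancestral allele;"
      " observed fixation points to long isolation\n")

arms = iso.scenario_actn3(seed=13, n_replicates=1000)
for name, ens in arms.items():
    pct = ens.summary["percent_terminal_at_threshold"]
    ever = ens.summary["percent_ever_at_threshold"]
    print(f"ACTN3, {name} arm (p0=0.47, threshold 0.93):")
    print(f"  {pct:.1f}% of replicates at/above 0.93 at generation 500 "
          f"({ever:.1f}% ever reached it; first recorded hit: "
          f"generation {ens.first_hit_generation})")
print("  => the observed 93% frequency is reached routinely only with selection")
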