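"""Difference spectra isolate substituent-induced bands.

Subtracting the benzene analog from the toluene analog leaves a positive
lobe where the methyl combination band appears (2330 nm) and a negative lobe
where the ring band weakens (2460 nm).
"""

from nirassign import difference_spectrum
from nirassign.synthetic import make_methylbenzene_family, simulate_spectrum

family = {c.name: c for c in make_methylbenzene_family()}
toluene = simulate_spectrum(family["toluene"], concentration=1.0)
benzene = simulate_spectrum(family["benzene"], concentration=1.0)

ds = difference_spectrum(toluene, benzene)
for nm in (1670.0, 2330.0, 2460.0):
    sign = "+" if ds.value_at(nm) > 0 else "-"
    print(f"  {nm:6.0f} nm  delta A = {ds.value_at(nm):+8.4f}  ({sign})")
print("\nPositive at 2330 nm: the methyl band toluene has and benzene lacks."
      "\nNegative at 2460 nm: the strong benzene ring band is weaker in toluene.")
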