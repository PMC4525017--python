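"""Virtual PCR with the packaged degenerate hemA screening primers.

Builds one synthetic cyclizing-ALAS gene, one off-target template and one
negative, and runs the HemA1/HemA3 pair on each.  The cALAS template
yields the single canonical 519 bp band; the off-target runs slightly
smaller; the negative gives nothing.
"""

from c5nscreen.primers import HEMA1, HEMA3, expand_degenerate, in_silico_pcr
from c5nscreen.synthetic import SynthesisConfig, synth_alas_gene

cfg = SynthesisConfig(seed=1)
print(f"{HEMA1.name}: {HEMA1.sequence} (degeneracy {HEMA1.degeneracy})")
print(f"{HEMA3.name}: {HEMA3.sequence} (degeneracy {len(expand_degenerate(HEMA3))})")
print()

for label in ("cALAS_purple", "AONS_offtarget", "negative"):
    rec = synth_alas_gene(label, cfg)
    products = in_silico_pcr(rec.cds, HEMA1, HEMA3, max_mismatches=0)
    bands = ", ".join(f"{p.length} bp ({p.size_class})" for p in products) or "no product"
    print(f"{label:18s} -> {bands}")

print()
print("One band of invariable size marks a hemA-positive template; a")
print("slightly smaller band flags an aminolevulinate-related off-target.")
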