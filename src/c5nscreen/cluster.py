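"""C5N gene-triad detection, GC content and horizontal-transfer flags.

The C5N biosynthetic triad comprises the amide synthase (*ams*), the
cyclizing ALAS (*hemA*) and the aminolevulinate-CoA ligase (*all*) genes.
Producer genomes carry it in two canonical layouts: head-to-tail
ams-hemA-all on one strand ("purple"-group producers of simple linear
polyketides) or hemA on the opposite strand upstream of the ams-all pair
("green"-group producers of complex polyketides).  Anything else with all
three genes present is atypical; fewer than three is incomplete.

Classical (non-cyclizing) hemA genes in high-GC actinomycete genomes are
screened for horizontal-transfer signal by the GC content of the gene
itself: above the 62% threshold the gene groups with GC-rich bacterial
donors (blue branch I), at or below it with low-GC donors such as fungi
(blue branch II).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as _iproduct
from typing import Iterable, Literal, Sequence

from ._codons import gc_fraction

__all__ = [
    "GeneFeature",
    "TriadCall",
    "HgtFlag",
    "detect_triad",
    "gc_percent",
    "hgt_classify",
    "read_gff3",
    "write_gff3",
    "GC_HGT_THRESHOLD",
    "DEFAULT_MAX_GAP",
]

#: GC% split between blue branch I (GC-rich donors) and II (low-GC donors)
GC_HGT_THRESHOLD = 62.0
#: maximum intergenic gap (nt) for triad genes to count as adjacent
DEFAULT_MAX_GAP = 1000

TRIAD_LABELS = ("ams", "hemA", "all")


@dataclass(frozen=True)
class GeneFeature:
    """An annotated gene on a contig; 0-based half-open coordinates."""

    id: str
    label: Literal["ams", "hemA", "all", "other"]
    contig_id: str
    start: int
    end: int
    strand: Literal["+", "-"]

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"feature {self.id}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.id}: strand must be + or -")


@dataclass(frozen=True)
class TriadCall:
    """The matched triad genes (any subset) and the arrangement verdict."""

    genes: dict[str, GeneFeature]
    arrangement: Literal["head_to_tail", "divergent", "atypical", "incomplete"]
    max_gap: int | None


def _gap(left: GeneFeature, right: GeneFeature) -> int:
    return max(0, right.start - left.end)


def detect_triad(features: Iterable[GeneFeature], max_gap: int = DEFAULT_MAX_GAP) -> TriadCall:
    """Type the ams/hemA/all arrangement among *features* of one contig.

    head_to_tail: the three genes adjacent (intergenic gaps <= *max_gap*),
    on one strand, reading ams -> hemA -> all along that strand.
    divergent: ams and all adjacent on one strand (ams first along it),
    hemA on the opposite strand upstream of the pair, within *max_gap*.
    All three present in any other layout: atypical; otherwise incomplete.

    When a label occurs on several features, the combination spanning the
    smallest region is analysed (nearest-neighbour grouping); identical
    labels overlapping each other are rejected.
    """
    by_label: dict[str, list[GeneFeature]] = {lab: [] for lab in TRIAD_LABELS}
    for f in features:
        if f.label in by_label:
            by_label[f.label].append(f)
    for lab, fs in by_label.items():
        fs.sort(key=lambda f: f.start)
        for a, b in zip(fs, fs[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping features with identical label {lab!r}")
    present = [lab for lab in TRIAD_LABELS if by_label[lab]]
    # nearest-neighbour grouping: minimise the genomic span of the chosen combo
    combos = _iproduct(*(by_label[lab] for lab in present))
    chosen = min(
        combos, key=lambda c: max(f.end for f in c) - min(f.start for f in c)
    )
    genes = dict(zip(present, chosen))
    if len(present) < 3:
        return TriadCall(genes, "incomplete", None)

    ams, hemA, all_ = (genes[lab] for lab in TRIAD_LABELS)
    ordered = sorted(genes.values(), key=lambda f: f.start)
    gaps = [_gap(a, b) for a, b in zip(ordered, ordered[1:])]
    worst = max(gaps)

    same_strand = len({f.strand for f in ordered}) == 1
    if same_strand and worst <= max_gap:
        order = [f.label for f in ordered]
        strand = ordered[0].strand
        if (strand == "+" and order == ["ams", "hemA", "all"]) or (
            strand == "-" and order == ["all", "hemA", "ams"]
        ):
            return TriadCall(genes, "head_to_tail", worst)

    if ams.strand == all_.strand and hemA.strand != ams.strand:
        s = ams.strand
        pair_ok = (s == "+" and ams.end <= all_.start and _gap(ams, all_) <= max_gap) or (
            s == "-" and all_.end <= ams.start and _gap(all_, ams) <= max_gap
        )
        if pair_ok:
            if s == "+" and hemA.end <= ams.start and _gap(hemA, ams) <= max_gap:
                return TriadCall(genes, "divergent", worst)
            if s == "-" and ams.end <= hemA.start and _gap(ams, hemA) <= max_gap:
                return TriadCall(genes, "divergent", worst)

    return TriadCall(genes, "atypical", worst)


def gc_percent(seq: str) -> float:
    """GC content in percent; Ns are excluded from the denominator."""
    if not seq:
        raise ValueError("empty sequence")
    return 100.0 * gc_fraction(seq)


@dataclass(frozen=True)
class HgtFlag:
    gc_percent: float
    branch: Literal["blue_I", "blue_II", "none"]


def hgt_classify(verdict: str, gc: float, threshold: float = GC_HGT_THRESHOLD) -> HgtFlag:
    """Assign a non-cALAS gene to a blue (horizontally transferred) branch.

    GC above *threshold* -> blue_I, otherwise blue_II; equality goes to
    blue_II so the rule is total.  cALAS verdicts are never flagged.
    """
    if not 0.0 <= gc <= 100.0:
        raise ValueError("gc must be a percentage in [0, 100]")
    if verdict == "cALAS":
        return HgtFlag(gc, "none")
    return HgtFlag(gc, "blue_I" if gc > threshold else "blue_II")


# ---------------------------------------------------------------------------
# GFF3 I/O (1-based inclusive on disk, 0-based half-open in memory)

def write_gff3(features: Sequence[GeneFeature], path, contig_lengths: dict[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if contig_lengths:
            for cid, n in contig_lengths.items():
                fh.write(f"##sequence-region {cid} 1 {n}\n")
        for f in sorted(features, key=lambda f: (f.contig_id, f.start)):
            fh.write(
                f"{f.contig_id}\tc5nscreen\tgene\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t"
                f"ID={f.id};label={f.label}\n"
            )


def read_gff3(path) -> dict[str, list[GeneFeature]]:
    """Read gene/CDS features keyed by contig; the ``label`` attribute
    (ams/hemA/all) drives triad detection, anything else becomes 'other'."""
    import gffutils

    out: dict[str, list[GeneFeature]] = {}
    for feat in gffutils.iterators.DataIterator(str(path)):
        if feat.featuretype not in ("gene", "CDS"):
            continue
        label = (feat.attributes.get("label") or ["other"])[0]
        if label not in TRIAD_LABELS:
            label = "other"
        fid = (feat.attributes.get("ID") or [f"{feat.seqid}:{feat.start}"])[0]
        out.setdefault(feat.seqid, []).append(
            GeneFeature(fid, label, feat.seqid, feat.start - 1, feat.end, feat.strand)
        )
    return out


def read_feature_table(path) -> dict[str, list[GeneFeature]]:
    """5-column TSV alternative: contig_id, id, label, start, end, strand
    (header optional; coordinates 0-based half-open)."""
    out: dict[str, list[GeneFeature]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("contig_id"):
                continue
            cid, fid, label, start, end, strand = line.split("\t")
            if label not in TRIAD_LABELS:
                label = "other"
            out.setdefault(cid, []).append(GeneFeature(fid, label, cid, int(start), int(end), strand))
    return out


def write_triad_report(calls: dict[str, TriadCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tarrangement\tmax_gap\tams\themA\tall\n")
        for cid, call in sorted(calls.items()):
            cells = [
                f"{g.start}-{g.end}({g.strand})" if (g := call.genes.get(lab)) else "."
                for lab in TRIAD_LABELS
            ]
            gap = "." if call.max_gap is None else str(call.max_gap)
            fh.write(f"{cid}\t{call.arrangement}\t{gap}\t" + "\t".join(cells) + "\n")
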