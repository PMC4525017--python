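"""Degenerate primers and virtual PCR on nucleotide templates.

This module models the hemA screening assay in silico: IUPAC-degenerate
oligonucleotides, annealing-site search on both template strands with a
mismatch budget and a mandatory exact 3'-end, and amplicon extraction from
convergent primer pairs.  Product sizes are binned against the canonical
519 bp hemA band; slightly smaller products flag likely
8-amino-7-oxononanoate synthase (AONS) off-targets.

Matching semantics
------------------
A primer position is compatible with a template position when the IUPAC
base sets intersect.  Template Ns are treated conservatively: they match
nothing and always count as a mismatch.  Reverse-strand hits are reported
in forward-template coordinates (0-based, half-open).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal

import numpy as np

from ._codons import revcomp

__all__ = [
    "IUPAC_SETS",
    "DegeneratePrimer",
    "PrimerHit",
    "Amplicon",
    "HEMA1",
    "HEMA3",
    "expand_degenerate",
    "iupac_match",
    "in_silico_pcr",
    "classify_product_size",
    "CANONICAL_PRODUCT_BP",
    "DEFAULT_SIZE_WINDOW",
    "DEFAULT_OFFTARGET_BAND",
]

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_MASK = {code: sum(_BITS[b] for b in bases) for code, bases in IUPAC_SETS.items()}

#: length in bp of the single hemA screening band, both primer footprints included
CANONICAL_PRODUCT_BP = 519
DEFAULT_SIZE_WINDOW = (300, 800)
#: AONS off-targets run "slightly smaller"; bp below canonical that still flags them
DEFAULT_OFFTARGET_BAND = (20, 120)


@dataclass(frozen=True)
class DegeneratePrimer:
    """An IUPAC-degenerate oligonucleotide with an assay role."""

    name: str
    sequence: str
    role: Literal["forward", "reverse"]

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError("primer sequence must be nonempty")
        bad = set(seq) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"non-IUPAC characters in primer {self.name!r}: {sorted(bad)}")
        if self.role not in ("forward", "reverse"):
            raise ValueError(f"role must be forward or reverse, got {self.role!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def degeneracy(self) -> int:
        """Number of concrete sequences the primer represents."""
        n = 1
        for b in self.sequence:
            n *= len(IUPAC_SETS[b])
        return n


# The two screening primers as printed, with the HemA1 "S/R" position read as
# the union of the S and R base sets (= IUPAC V).  See expand_two_variant()
# for the alternative two-oligo reading.
HEMA1 = DegeneratePrimer("HemA1", "GTSTGGTGYTCVGSAACGACTACCT", "forward")
HEMA3 = DegeneratePrimer("HemA3", "GTACATSCCSACSGCGTGSACCTCGCT", "reverse")


def expand_degenerate(primer: DegeneratePrimer | str) -> set[str]:
    """All concrete sequences matching the degenerate pattern.

    The cardinality of the returned set equals the product of the
    per-position ambiguity set sizes.
    """
    seq = primer.sequence if isinstance(primer, DegeneratePrimer) else str(primer).upper()
    bad = set(seq) - set(IUPAC_SETS)
    if bad:
        raise ValueError(f"non-IUPAC characters: {sorted(bad)}")
    variants = [""]
    for code in seq:
        variants = [v + b for v in variants for b in sorted(IUPAC_SETS[code])]
    return set(variants)


def expand_two_variant(primer: DegeneratePrimer, position: int, first: str, second: str) -> tuple[DegeneratePrimer, DegeneratePrimer]:
    """Split one ambiguous position into two primer variants (e.g. S/R)."""
    seq = primer.sequence
    a = seq[:position] + first + seq[position + 1 :]
    b = seq[:position] + second + seq[position + 1 :]
    return (
        replace(primer, name=f"{primer.name}a", sequence=a),
        replace(primer, name=f"{primer.name}b", sequence=b),
    )


@dataclass(frozen=True)
class PrimerHit:
    """One annealing site in forward-template coordinates (0-based, half-open)."""

    template_id: str
    primer_name: str
    start: int
    end: int
    strand: Literal["+", "-"]
    mismatches: int
    three_prime_exact: bool


def _encode(seq: str, n_matches_nothing: bool) -> np.ndarray:
    seq = seq.upper()
    table = np.zeros(256, dtype=np.uint8)
    for code, mask in _MASK.items():
        table[ord(code)] = mask
    if n_matches_nothing:
        table[ord("N")] = 0
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return table[arr]


def _scan(tmpl_mask: np.ndarray, primer_seq: str, max_mismatches: int, exact_tail: slice) -> list[tuple[int, int]]:
    """Return (start, mismatches) for windows within budget and exact in exact_tail."""
    p = _encode(primer_seq, n_matches_nothing=False)
    L, m = len(tmpl_mask), len(p)
    if m > L:
        return []
    n_win = L - m + 1
    mism = np.zeros(n_win, dtype=np.int32)
    tail_mism = np.zeros(n_win, dtype=np.int32)
    tail_idx = set(range(*exact_tail.indices(m)))
    for i in range(m):
        bad = (tmpl_mask[i : i + n_win] & p[i]) == 0
        mism += bad
        if i in tail_idx:
            tail_mism += bad
    ok = (mism <= max_mismatches) & (tail_mism == 0)
    return [(int(s), int(mism[s])) for s in np.nonzero(ok)[0]]


def iupac_match(
    template: str,
    primer: DegeneratePrimer,
    max_mismatches: int = 2,
    require_3prime_exact: int = 3,
    template_id: str = "",
) -> list[PrimerHit]:
    """Find annealing sites for *primer* on both strands of *template*.

    A site is reported iff its IUPAC-compatibility Hamming distance is
    <= ``max_mismatches`` and the primer's 3'-terminal
    ``require_3prime_exact`` bases match with zero mismatches (mimicking
    the polymerase-extension requirement).  Hits are sorted by (start,
    strand).  A primer longer than the template yields an empty list.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    template = template.upper()
    bad = set(template) - set("ACGTN")
    if bad:
        raise ValueError(f"template must be over ACGTN, found {sorted(bad)}")
    tmask = _encode(template, n_matches_nothing=True)
    m = len(primer)
    r3 = min(max(require_3prime_exact, 0), m)
    hits: list[PrimerHit] = []
    # + strand: primer as written, 3' end is the window's right edge
    for start, mm in _scan(tmask, primer.sequence, max_mismatches, slice(m - r3, m)):
        hits.append(PrimerHit(template_id, primer.name, start, start + m, "+", mm, True))
    # - strand: reverse complement of the primer, 3' end at the window's left edge
    for start, mm in _scan(tmask, revcomp(primer.sequence), max_mismatches, slice(0, r3)):
        hits.append(PrimerHit(template_id, primer.name, start, start + m, "-", mm, True))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


@dataclass(frozen=True)
class Amplicon:
    """A virtual PCR product; outer coordinates include both primer footprints."""

    template_id: str
    start: int
    end: int
    strand: Literal["+", "-"]
    sequence: str
    fwd_hit: PrimerHit
    rev_hit: PrimerHit
    size_class: Literal["on_target", "smaller_offtarget", "other"] = "other"

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def mismatches(self) -> int:
        return self.fwd_hit.mismatches + self.rev_hit.mismatches


def classify_product_size(
    length: int | Amplicon,
    canonical: int = CANONICAL_PRODUCT_BP,
    offtarget_band: tuple[int, int] = DEFAULT_OFFTARGET_BAND,
) -> str:
    """Bin a product length against the canonical band.

    ``on_target`` iff the length equals the canonical size exactly (the
    screening band shows "no variation in size"); ``smaller_offtarget``
    iff the deficit falls in *offtarget_band* bp, the signature of AONS
    amplification; ``other`` otherwise.
    """
    if canonical <= 0:
        raise ValueError("canonical size must be positive")
    if isinstance(length, Amplicon):
        length = length.length
    if length == canonical:
        return "on_target"
    deficit = canonical - length
    if offtarget_band[0] <= deficit <= offtarget_band[1]:
        return "smaller_offtarget"
    return "other"


def in_silico_pcr(
    template: str,
    fwd: DegeneratePrimer = HEMA1,
    rev: DegeneratePrimer = HEMA3,
    size_window: tuple[int, int] = DEFAULT_SIZE_WINDOW,
    max_mismatches: int = 2,
    require_3prime_exact: int = 3,
    template_id: str = "",
    canonical: int = CANONICAL_PRODUCT_BP,
    offtarget_band: tuple[int, int] = DEFAULT_OFFTARGET_BAND,
) -> list[Amplicon]:
    """Enumerate products of a convergent fwd/rev primer pair on *template*.

    Both template orientations are handled; product sequences are reported
    5'->3' with respect to the forward primer.  Products outside
    *size_window* are discarded.  Returns an empty list when no convergent
    pair exists.
    """
    if size_window[0] < len(fwd) + len(rev):
        raise ValueError("size_window minimum must be >= combined primer length")
    template = template.upper()
    fhits = iupac_match(template, fwd, max_mismatches, require_3prime_exact, template_id)
    rhits = iupac_match(template, rev, max_mismatches, require_3prime_exact, template_id)
    products: list[Amplicon] = []
    # forward primer on + strand, reverse primer annealing on - strand to its right
    for f in (h for h in fhits if h.strand == "+"):
        for r in (h for h in rhits if h.strand == "-" and h.start >= f.end):
            span = r.end - f.start
            if size_window[0] <= span <= size_window[1]:
                products.append(
                    Amplicon(
                        template_id, f.start, r.end, "+",
                        template[f.start : r.end], f, r,
                        classify_product_size(span, canonical, offtarget_band),
                    )
                )
    # mirrored orientation: product read off the - strand
    for f in (h for h in fhits if h.strand == "-"):
        for r in (h for h in rhits if h.strand == "+" and h.end <= f.start):
            span = f.end - r.start
            if size_window[0] <= span <= size_window[1]:
                products.append(
                    Amplicon(
                        template_id, r.start, f.end, "-",
                        revcomp(template[r.start : f.end]), f, r,
                        classify_product_size(span, canonical, offtarget_band),
                    )
                )
    products.sort(key=lambda a: (a.start, a.end, a.strand))
    return products


def write_amplicons_fasta(amplicons: Iterable[Amplicon], path) -> None:
    """Write products as FASTA with ids ``template_id|start-end|strand``."""
    with open(path, "w") as fh:
        for a in amplicons:
            fh.write(f">{a.template_id}|{a.start}-{a.end}|{a.strand}\n{a.sequence}\n")


def write_hit_table(amplicons: Iterable[Amplicon], path) -> None:
    """TSV product table (one row per amplicon)."""
    cols = "template_id\tstart\tend\tstrand\tlength\tmismatches_fwd\tmismatches_rev\tsize_class\n"
    with open(path, "w") as fh:
        fh.write(cols)
        for a in amplicons:
            fh.write(
                f"{a.template_id}\t{a.start}\t{a.end}\t{a.strand}\t{a.length}\t"
                f"{a.fwd_hit.mismatches}\t{a.rev_hit.mismatches}\t{a.size_class}\n"
            )
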