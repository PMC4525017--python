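"""Codon tables and small nucleotide helpers shared across modules.

The genetic code is taken from Biopython's standard table; for the coding
sequences handled here (bacterial CDS fragments translated internally) the
standard and bacterial tables are identical apart from start codons, which
never matter for internal translation.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid (one-letter); stop codons excluded
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

#: amino acid -> tuple of synonymous codons, in fixed (sorted) order
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] += (_codon,)

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement over the full IUPAC nucleotide alphabet."""
    return seq.translate(COMPLEMENT)[::-1]


def translate_nt(seq: str) -> str:
    """Translate a nucleotide string codon by codon.

    Trailing incomplete codons are dropped; any codon containing a
    character outside ACGT (e.g. N) yields X; stop codons yield '*'.
    """
    seq = seq.upper()
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if codon in CODON_TO_AA:
            out.append(CODON_TO_AA[codon])
        elif codon in STOP_CODONS:
            out.append("*")
        else:
            out.append("X")
    return "".join(out)


def gc_fraction(seq: str) -> float:
    """GC fraction over unambiguous bases (Ns excluded from the denominator)."""
    seq = seq.upper()
    atgc = sum(seq.count(b) for b in "ACGT")
    if atgc == 0:
        raise ValueError("sequence has no unambiguous bases")
    return (seq.count("G") + seq.count("C")) / atgc
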