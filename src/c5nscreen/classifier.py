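"""Diagnostic-residue classification of aminolevulinate synthases.

Cyclizing ALAS (cALAS), the enzyme that forms the C5N unit
(2-amino-3-hydroxycyclopent-2-enone), differs from classical
primary-metabolism ALAS at a small set of strictly conserved residues;
the key substitution is Thr->Ser at reference position 83 in the active
site, supported by Ile->Leu/Val at 149, Asp->Thr at 231 and Thr->Ser at
365.  This module aligns a query protein (full gene product or translated
519-bp amplicon) to a packaged reference, reads the residue states at the
panel positions, and returns a cALAS / classical / indeterminate verdict.
It also provides the genome-scanning homology pre-filter (identity >= 40%
and similarity >= 60% by default).

Positions are defined in the coordinates of the packaged synthetic
reference protein; the panel is a YAML document and can be swapped
wholesale for a different reference and numbering.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Literal, Mapping

import yaml
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from ._codons import translate_nt

__all__ = [
    "DiagnosticPosition",
    "DiagnosticPanel",
    "AlignmentResult",
    "ResidueCalls",
    "AlasClassification",
    "load_default_panel",
    "translate_amplicon",
    "pick_frame",
    "align_to_reference",
    "call_diagnostics",
    "classify_alas",
    "homology_prefilter",
]

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class DiagnosticPosition:
    """One diagnostic residue in reference coordinates (1-based)."""

    ref_position: int
    classical_residue: str
    calas_residues: frozenset[str]
    weight: float = 1.0
    mandatory: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "calas_residues", frozenset(self.calas_residues))
        if self.classical_residue in self.calas_residues:
            raise ValueError(
                f"position {self.ref_position}: classical residue cannot also be cALAS-diagnostic"
            )
        if self.weight < 0:
            raise ValueError("weight must be nonnegative")


@dataclass(frozen=True)
class DiagnosticPanel:
    """The diagnostic panel plus the reference protein it is numbered against."""

    reference_id: str
    reference_protein: str
    positions: tuple[DiagnosticPosition, ...]
    extended_positions: tuple[DiagnosticPosition, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.reference_protein)
        for p in self.all_positions:
            if not 1 <= p.ref_position <= n:
                raise ValueError(f"panel position {p.ref_position} outside reference (length {n})")
        if sum(p.mandatory for p in self.positions) != 1:
            raise ValueError("panel must have exactly one mandatory core position")

    @property
    def all_positions(self) -> tuple[DiagnosticPosition, ...]:
        return self.positions + self.extended_positions

    @property
    def mandatory_position(self) -> DiagnosticPosition:
        return next(p for p in self.positions if p.mandatory)


def load_default_panel() -> DiagnosticPanel:
    """Load the packaged panel (four core positions) and its reference protein."""
    data = resources.files("c5nscreen").joinpath("data")
    cfg = yaml.safe_load(data.joinpath("panel.yaml").read_text())
    with resources.as_file(data.joinpath(cfg["reference_fasta"])) as path:
        record = next(SeqIO.parse(str(path), "fasta"))
    return panel_from_dict(cfg, str(record.seq))


def panel_from_dict(cfg: Mapping, reference_protein: str) -> DiagnosticPanel:
    def mk(d: Mapping) -> DiagnosticPosition:
        return DiagnosticPosition(
            ref_position=int(d["ref_position"]),
            classical_residue=str(d["classical_residue"]),
            calas_residues=frozenset(str(r) for r in d["calas_residues"]),
            weight=float(d.get("weight", 1.0)),
            mandatory=bool(d.get("mandatory", False)),
        )

    return DiagnosticPanel(
        reference_id=str(cfg["reference_id"]),
        reference_protein=reference_protein,
        positions=tuple(mk(d) for d in cfg["positions"]),
        extended_positions=tuple(mk(d) for d in cfg.get("extended_positions") or ()),
    )


def translate_amplicon(nt: str, frame: int = 0) -> tuple[str, bool]:
    """Translate a nucleotide fragment in the given frame.

    Returns (protein, internal_stop_flag).  Trailing incomplete codons are
    dropped and codons containing N translate to X.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    aa = translate_nt(nt[frame:])
    return aa, "*" in aa


def pick_frame(nt: str) -> int:
    """Pick the translation frame: 0 unless it contains an internal stop.

    By primer design the canonical amplicon starts on a codon boundary, so
    frame 0 is preferred; otherwise the first stop-free frame wins, and if
    every frame has stops, the one with fewest.
    """
    stops = []
    for frame in (0, 1, 2):
        aa, _ = translate_amplicon(nt, frame)
        if "*" not in aa:
            return frame
        stops.append(aa.count("*"))
    return int(min(range(3), key=lambda f: stops[f]))


def _make_aligner(open_gap: float, extend_gap: float, matrix) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -abs(open_gap)
    aligner.extend_gap_score = -abs(extend_gap)
    aligner.end_gap_score = 0.0  # semi-global: fragments map freely onto the reference
    return aligner


@dataclass(frozen=True)
class AlignmentResult:
    """Global alignment of a query onto a reference, with a position map.

    ``ref_to_query`` maps 1-based reference positions to 0-based query
    indices for aligned (non-gap) columns; identity and similarity are
    percentages over aligned columns (similarity = columns with a positive
    substitution-matrix score).
    """

    score: float
    identity: float
    similarity: float
    ref_to_query: Mapping[int, int]
    aligned_ref_span: tuple[int, int]  # first/last aligned reference position, 1-based

    def state_at(self, ref_position: int, query: str) -> str:
        """Query residue aligned to *ref_position*, or 'gap' / 'unaligned'."""
        if ref_position in self.ref_to_query:
            return query[self.ref_to_query[ref_position]]
        lo, hi = self.aligned_ref_span
        return "gap" if lo <= ref_position <= hi else "unaligned"


def align_to_reference(
    query_protein: str,
    reference_protein: str,
    open_gap: float = 10.0,
    extend_gap: float = 1.0,
    matrix=_BLOSUM62,
) -> AlignmentResult:
    """Align *query* to *reference* (affine gaps, BLOSUM62 by default).

    A gap of length L costs open + (L-1)*extend; terminal gaps are free so
    that amplicon-sized fragments map onto the full-length reference.
    """
    if not query_protein or not reference_protein:
        raise ValueError("sequences must be nonempty")
    aligner = _make_aligner(open_gap, extend_gap, matrix)
    alignment = aligner.align(reference_protein, query_protein)[0]
    ref_blocks, query_blocks = alignment.aligned
    ref_to_query: dict[int, int] = {}
    identical = similar = aligned_cols = 0
    for (rs, re), (qs, _qe) in zip(ref_blocks, query_blocks):
        for off in range(re - rs):
            r, q = reference_protein[rs + off], query_protein[qs + off]
            ref_to_query[rs + off + 1] = qs + off
            aligned_cols += 1
            if r == q:
                identical += 1
            try:
                if matrix[r, q] > 0:
                    similar += 1
            except IndexError:  # residue outside the matrix alphabet
                pass
    if aligned_cols == 0:
        raise ValueError("alignment has no aligned columns")
    span = (min(ref_to_query), max(ref_to_query))
    return AlignmentResult(
        score=float(alignment.score),
        identity=100.0 * identical / aligned_cols,
        similarity=100.0 * similar / aligned_cols,
        ref_to_query=ref_to_query,
        aligned_ref_span=span,
    )


@dataclass(frozen=True)
class ResidueCalls:
    """Observed query states at the panel positions.

    ``states`` maps reference position -> single-letter residue, 'gap', or
    'unaligned'; the three counters partition the panel positions.
    """

    states: Mapping[int, str]
    calas_consistent: int
    classical_consistent: int
    other: int

    def category(self, position: DiagnosticPosition) -> str:
        state = self.states[position.ref_position]
        if state in position.calas_residues:
            return "calas"
        if state == position.classical_residue:
            return "classical"
        return "other"


def call_diagnostics(result: AlignmentResult, query_protein: str, panel: DiagnosticPanel) -> ResidueCalls:
    """Read the query residue aligned to each panel position."""
    states: dict[int, str] = {}
    n_cal = n_cls = n_oth = 0
    for p in panel.all_positions:
        state = result.state_at(p.ref_position, query_protein)
        states[p.ref_position] = state
        if state in p.calas_residues:
            n_cal += 1
        elif state == p.classical_residue:
            n_cls += 1
        else:
            n_oth += 1
    return ResidueCalls(states, n_cal, n_cls, n_oth)


@dataclass(frozen=True)
class AlasClassification:
    verdict: Literal["cALAS", "classical", "indeterminate"]
    score: float
    calls: ResidueCalls


def classify_alas(
    calls: ResidueCalls,
    panel: DiagnosticPanel,
    min_supporting: int = 2,
) -> AlasClassification:
    """Derive the verdict from the residue calls.

    cALAS: the mandatory position is cALAS-consistent and at least
    ``min_supporting`` of the remaining core positions are too.

    classical: the mandatory position and every *observed* core position
    are classical-consistent.  Amplicon-sized fragments only cover part of
    the reference, so positions outside the aligned region (state
    'unaligned') do not block the classical verdict; a cALAS-consistent or
    deviant observed residue does.

    Anything else is indeterminate.  The score is the weighted
    cALAS-consistent fraction over all panel positions.
    """
    mand = panel.mandatory_position
    others = [p for p in panel.positions if not p.mandatory]
    cat = calls.category
    n_support = sum(cat(p) == "calas" for p in others)
    if cat(mand) == "calas" and n_support >= min_supporting:
        verdict = "cALAS"
    else:
        observed = [p for p in panel.positions if calls.states[p.ref_position] not in ("gap", "unaligned")]
        if observed and all(cat(p) == "classical" for p in observed) and mand in observed:
            verdict = "classical"
        else:
            verdict = "indeterminate"
    total_w = sum(p.weight for p in panel.all_positions) or 1.0
    score = sum(p.weight for p in panel.all_positions if cat(p) == "calas") / total_w
    return AlasClassification(verdict, score, calls)


@dataclass(frozen=True)
class PrefilterResult:
    passed: bool
    identity: float
    similarity: float


def homology_prefilter(
    candidate_protein: str,
    query_protein: str,
    min_identity: float = 40.0,
    min_similarity: float = 60.0,
) -> PrefilterResult:
    """Genome-scanning pre-filter: keep candidates that align to the query
    with identity and similarity above the screening cutoffs."""
    res = align_to_reference(candidate_protein, query_protein)
    passed = res.identity >= min_identity and res.similarity >= min_similarity
    return PrefilterResult(passed, res.identity, res.similarity)


def classify_protein(
    query_protein: str,
    panel: DiagnosticPanel | None = None,
    min_supporting: int = 2,
) -> AlasClassification:
    """Convenience wrapper: align, call diagnostics, classify."""
    panel = panel or load_default_panel()
    result = align_to_reference(query_protein, panel.reference_protein)
    calls = call_diagnostics(result, query_protein, panel)
    return classify_alas(calls, panel, min_supporting)
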