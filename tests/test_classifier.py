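"""Translation, reference alignment, diagnostic calls and ALAS verdicts."""

import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from c5nscreen.classifier import (
    DiagnosticPanel,
    DiagnosticPosition,
    ResidueCalls,
    align_to_reference,
    call_diagnostics,
    classify_alas,
    classify_protein,
    homology_prefilter,
    pick_frame,
    translate_amplicon,
)

BLOSUM62 = substitution_matrices.load("BLOSUM62")


class TestTranslation:
    def test_standard_code(self):
        assert translate_amplicon("ATGGCT")[0] == "MA"

    def test_trailing_incomplete_codon_dropped_and_n_becomes_x(self):
        aa, stop = translate_amplicon("ATGGANCC")
        assert aa == "MX" and not stop

    def test_internal_stop_flagged(self):
        aa, stop = translate_amplicon("ATGTAAGCT")
        assert aa == "M*A" and stop

    def test_canonical_amplicon_translates_to_173_residues(self, cfg):
        from c5nscreen.primers import in_silico_pcr
        from c5nscreen.synthetic import synth_alas_gene

        rec = synth_alas_gene("cALAS_purple", cfg)
        product = in_silico_pcr(rec.cds)[0]
        aa, stop = translate_amplicon(product.sequence, 0)
        assert len(aa) == 519 // 3 == 173
        assert not stop
        assert pick_frame(product.sequence) == 0

    def test_frame_validation(self):
        with pytest.raises(ValueError):
            translate_amplicon("ATG", frame=3)


def brute_force_score(a, b, open_gap=10.0, extend_gap=1.0):
    """Enumerate every global alignment of a and b and score it with
    affine internal gaps (open + (L-1)*extend) and free end gaps."""

    best = -np.inf
    # a path is a sequence of moves: M (pair), D (gap in b), I (gap in a)
    def walk(i, j, path):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score(path))
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, path + "M")
        if i < len(a):
            walk(i + 1, j, path + "D")
        if j < len(b):
            walk(i, j + 1, path + "I")

    def score(path):
        total, ia, ib = 0.0, 0, 0
        for run_char, run in itertools.groupby(enumerate(path), key=lambda t: t[1]):
            run = list(run)
            start, end = run[0][0], run[-1][0] + 1
            L = len(run)
            if run_char == "M":
                for _ in range(L):
                    total += BLOSUM62[a[ia], b[ib]]
                    ia += 1
                    ib += 1
            else:
                if run_char == "D":
                    ia += L
                else:
                    ib += L
                if start > 0 and end < len(path):  # internal gap run
                    total -= open_gap + (L - 1) * extend_gap
        return total

    walk(0, 0, "")
    return best


class TestAlignment:
    def test_identical_sequences_give_identity_100_and_identity_map(self):
        res = align_to_reference("MKVLAT", "MKVLAT")
        assert res.identity == 100.0 and res.similarity == 100.0
        assert res.ref_to_query == {i + 1: i for i in range(6)}

    def test_single_deletion_shifts_downstream_map_by_one(self):
        ref = "MKVLATWQERS"
        query = ref[:4] + ref[5:]  # drop reference position 5
        res = align_to_reference(query, ref)
        for p in range(1, 5):
            assert res.ref_to_query[p] == p - 1
        for p in range(6, 12):
            assert res.ref_to_query[p] == p - 2
        assert res.state_at(5, query) == "gap"

    def test_identity_is_symmetric(self):
        a, b = "MKWVLATGHERS", "MKWVIATGHQRS"
        assert align_to_reference(a, b).identity == pytest.approx(align_to_reference(b, a).identity)

    @pytest.mark.parametrize("seed", range(6))
    def test_optimal_score_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        aas = list("ARNDCQEGHILKMFPSTWYV")
        a = "".join(rng.choice(aas, size=rng.integers(3, 7)))
        b = "".join(rng.choice(aas, size=rng.integers(3, 7)))
        assert align_to_reference(a, b).score == pytest.approx(brute_force_score(a, b))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_to_reference("", "MKV")


def make_calls(states, panel):
    n_cal = n_cls = n_oth = 0
    for p in panel.all_positions:
        s = states[p.ref_position]
        if s in p.calas_residues:
            n_cal += 1
        elif s == p.classical_residue:
            n_cls += 1
        else:
            n_oth += 1
    return ResidueCalls(states, n_cal, n_cls, n_oth)


class TestDiagnostics:
    def test_reference_itself_is_calas_consistent_everywhere(self, panel):
        # the packaged reference is a cALAS-type protein
        res = align_to_reference(panel.reference_protein, panel.reference_protein)
        calls = call_diagnostics(res, panel.reference_protein, panel)
        assert calls.calas_consistent == 4 and calls.classical_consistent == 0
        assert classify_alas(calls, panel).verdict == "cALAS"
        assert classify_alas(calls, panel).score == 1.0

    def test_classical_variant_called_classical(self, panel):
        ref = panel.reference_protein
        q = list(ref)
        for p in panel.positions:
            q[p.ref_position - 1] = p.classical_residue
        cls = classify_protein("".join(q), panel)
        assert cls.verdict == "classical"
        assert cls.calls.states[83] == "T"

    def test_ser_at_83_is_calas_consistent(self, panel):
        calls = make_calls({83: "S", 149: "I", 231: "D", 365: "T"}, panel)
        pos83 = next(p for p in panel.positions if p.ref_position == 83)
        assert calls.category(pos83) == "calas"

    def test_gap_spanning_a_position_reported_as_gap(self, panel):
        ref = panel.reference_protein
        query = ref[:225] + ref[240:]  # deletes position 231
        res = align_to_reference(query, ref)
        calls = call_diagnostics(res, query, panel)
        assert calls.states[231] == "gap"

    def test_counts_partition_the_panel(self, panel):
        states = {83: "S", 149: "Q", 231: "gap", 365: "T"}
        calls = make_calls(states, panel)
        assert calls.calas_consistent + calls.classical_consistent + calls.other == 4


class TestVerdictRule:
    def test_full_calas_pattern(self, panel):
        calls = make_calls({83: "S", 149: "L", 231: "T", 365: "S"}, panel)
        out = classify_alas(calls, panel)
        assert out.verdict == "cALAS" and out.score == 1.0

    def test_full_classical_pattern(self, panel):
        calls = make_calls({83: "T", 149: "I", 231: "D", 365: "T"}, panel)
        assert classify_alas(calls, panel).verdict == "classical"

    def test_mandatory_position_gates_the_calas_verdict(self, panel):
        calls = make_calls({83: "T", 149: "L", 231: "T", 365: "S"}, panel)
        assert classify_alas(calls, panel).verdict == "indeterminate"

    def test_insufficient_support_is_indeterminate(self, panel):
        calls = make_calls({83: "S", 149: "L", 231: "D", 365: "T"}, panel)
        assert classify_alas(calls, panel).verdict == "indeterminate"

    def test_unobserved_positions_do_not_block_classical(self, panel):
        calls = make_calls({83: "T", 149: "I", 231: "D", 365: "unaligned"}, panel)
        assert classify_alas(calls, panel).verdict == "classical"

    def test_flipping_classical_to_calas_never_demotes_a_calas_verdict(self, panel):
        base = {83: "S", 149: "L", 231: "D", 365: "S"}
        assert classify_alas(make_calls(base, panel), panel).verdict == "cALAS"
        for pos, calas in [(149, "V"), (231, "T"), (365, "S")]:
            flipped = dict(base)
            flipped[pos] = calas
            assert classify_alas(make_calls(flipped, panel), panel).verdict == "cALAS"


class TestPanelIntegrity:
    def test_packaged_panel_shape(self, panel):
        assert len(panel.positions) == 4
        assert [p.ref_position for p in panel.positions] == [83, 149, 231, 365]
        assert panel.mandatory_position.ref_position == 83
        assert len(panel.reference_protein) == 400
        # reference carries the cALAS state at every panel position
        for p in panel.positions:
            assert panel.reference_protein[p.ref_position - 1] in p.calas_residues

    def test_invalid_panels_rejected(self):
        with pytest.raises(ValueError):
            DiagnosticPosition(83, "T", frozenset("T"))
        with pytest.raises(ValueError):
            DiagnosticPanel("x", "MKV", (DiagnosticPosition(5, "T", frozenset("S"), mandatory=True),))


class TestPrefilter:
    def test_identity_passes_itself(self):
        res = homology_prefilter("MKVLATWQE", "MKVLATWQE")
        assert res.passed and res.identity == 100.0 and res.similarity == 100.0

    def test_boundary_agrees_with_recomputed_metrics(self, panel):
        rng = np.random.default_rng(11)
        query = panel.reference_protein
        aas = list("ARNDCQEGHILKMFPSTWYV")
        for frac in (0.1, 0.3, 0.5, 0.65, 0.8):
            q = list(query)
            idx = rng.choice(len(q), size=int(frac * len(q)), replace=False)
            for i in idx:
                q[i] = rng.choice([a for a in aas if a != q[i]])
            cand = "".join(q)
            res = homology_prefilter(cand, query)
            check = align_to_reference(cand, query)
            assert res.passed == (check.identity >= 40.0 and check.similarity >= 60.0)
            assert res.identity == pytest.approx(check.identity)
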