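import math

import numpy as np
import pytest

from firetrace import iupac
from firetrace.align import ConsensusSequence
from firetrace.io import SequenceRecord
from firetrace.motifs import (PFM, PWM, find_core_element, group_by_family,
                              iupac_scan, pfm_to_pwm, read_jaspar, scan_pwm)

from conftest import random_seq

JASPAR_ONE = """>MA0001.1 TESTA
A [ 10  0  0  5 ]
C [  0 10  0  5 ]
G [  0  0 10  0 ]
T [  0  0  0  0 ]
"""

JASPAR_TWO = JASPAR_ONE + """>MA0002.1 TESTB
A [ 1 2 3 4 5 ]
C [ 4 3 2 1 0 ]
G [ 0 0 0 0 0 ]
T [ 0 0 0 0 0 ]
"""

# counts shaped like the high-affinity PU.1/ETS site CACTTCCTT
PU1_JASPAR = """>SYN0001.1 PU1like
A [  2 90  2  2  2  2  2  4  4 ]
C [ 90  4 90  2  2 90 90 45 45 ]
G [  4  2  4  2  2  2  2  2  2 ]
T [  4  4  4 94 94  6  6 49 49 ]
"""


@pytest.fixture
def pu1_pwm(tmp_path):
    path = tmp_path / "pu1.jaspar"
    path.write_text(PU1_JASPAR)
    return pfm_to_pwm(read_jaspar(path)[0])


class TestReadJaspar:
    def test_minimal_four_column_pfm(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(JASPAR_ONE)
        pfms = read_jaspar(path)
        assert len(pfms) == 1
        assert pfms[0].length == 4
        assert pfms[0].counts[0, 0] == 10

    def test_two_matrices_order_preserved(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(JASPAR_TWO)
        pfms = read_jaspar(path)
        assert [p.matrix_id for p in pfms] == ["MA0001.1", "MA0002.1"]

    def test_zero_column_sum_rejected(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(
            ">MA0003.1 BAD\nA [ 1 0 1 1 ]\nC [ 0 0 0 0 ]\n"
            "G [ 0 0 0 0 ]\nT [ 1 0 1 1 ]\n")
        with pytest.raises(ValueError, match="zero column sum"):
            read_jaspar(path)

    def test_family_assignment_from_table(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(JASPAR_ONE)
        pfms = read_jaspar(path, {"MA0001.1": ("ETS", True)})
        assert pfms[0].family == "ETS"


class TestPfmToPwm:
    def test_uniform_pfm_uniform_background_all_zero(self):
        pfm = PFM("u", "u", np.full((4, 6), 5.0))
        pwm = pfm_to_pwm(pfm)
        assert np.allclose(pwm.weights, 0.0)

    def test_hand_computed_weights(self):
        counts = np.array([[8, 0], [0, 6], [2, 2], [0, 2]], dtype=float)
        counts = np.hstack([counts, counts])  # L=4 to satisfy the container
        pfm = PFM("h", "h", counts)
        pwm = pfm_to_pwm(pfm, pseudocount=0.8)
        # w(A, 0) = log2(((8 + 0.8*0.25) / (10 + 0.8)) / 0.25)
        expected = math.log2(((8 + 0.2) / 10.8) / 0.25)
        assert pwm.weights[0, 0] == pytest.approx(expected)
        expected_t = math.log2(((0 + 0.2) / 10.8) / 0.25)
        assert pwm.weights[3, 0] == pytest.approx(expected_t)

    def test_consensus_scores_maximal_everywhere(self):
        counts = np.zeros((4, 4))
        for i, b in enumerate("TGAC"):
            counts["ACGT".index(b), i] = 1.0
        pwm = pfm_to_pwm(PFM("s", "s", counts))
        consensus_w = [pwm.weights["ACGT".index(b), i] for i, b in enumerate("TGAC")]
        assert np.allclose(pwm.weights.max(axis=0), consensus_w)

    def test_nonpositive_pseudocount_rejected(self):
        pfm = PFM("u", "u", np.full((4, 4), 1.0))
        with pytest.raises(ValueError, match="pseudocount"):
            pfm_to_pwm(pfm, pseudocount=0.0)


def bruteforce_scan(pwm: PWM, seq: str, threshold: float):
    """Score every window with an explicit per-position loop."""
    hits = []
    L = pwm.length
    for start in range(len(seq) - L + 1):
        s = 0.0
        for k, c in enumerate(seq[start:start + L]):
            if c == "N":
                continue
            bases = sorted(iupac.CODE_TO_BASES[c])
            s += sum(pwm.weights["ACGT".index(b), k] for b in bases) / len(bases)
        rel = (s - pwm.smin) / (pwm.smax - pwm.smin)
        if rel >= threshold - 1e-12:
            hits.append((start, rel))
    return hits


class TestScanPwm:
    def test_consensus_string_scores_one(self, pu1_pwm):
        rec = SequenceRecord("s", "CACTTCCTT")
        hits = scan_pwm(pu1_pwm, rec, threshold=0.99, both_strands=False)
        assert len(hits) == 1
        assert hits[0].relative_score == pytest.approx(1.0)

    def test_threshold_one_without_consensus_no_hits(self, pu1_pwm, rng):
        rec = SequenceRecord("s", "GATTACAGATTACAGATTACA")
        assert scan_pwm(pu1_pwm, rec, threshold=1.0) == []

    def test_planted_site_found_at_offset(self, pu1_pwm):
        rng = np.random.default_rng(9)
        bg = random_seq(rng, 300)
        planted = bg[:137] + "CACTTCCTT" + bg[146:]
        hits = scan_pwm(pu1_pwm, SequenceRecord("s", planted), threshold=0.85)
        plus = [h for h in hits if h.strand == "+"]
        assert [h.start for h in plus] == [137]
        expected = bruteforce_scan(pu1_pwm, planted, 0.85)
        assert [(h.start, h.relative_score) for h in plus] == \
            [(s, pytest.approx(r)) for s, r in expected]

    def test_matches_bruteforce_scorer(self, rng):
        for _ in range(50):
            L = int(rng.integers(4, 10))
            counts = rng.integers(0, 20, size=(4, L)).astype(float)
            counts[:, counts.sum(axis=0) == 0] += 1.0
            pwm = pfm_to_pwm(PFM("r", "r", counts))
            seq = random_seq(rng, 60)
            got = scan_pwm(pwm, SequenceRecord("s", seq), threshold=0.8,
                           both_strands=False)
            expected = bruteforce_scan(pwm, seq, 0.8)
            assert [(h.start, round(h.relative_score, 10)) for h in got] == \
                [(s, round(r, 10)) for s, r in expected]

    def test_relative_score_invariant_under_affine_rescaling(self, pu1_pwm, rng):
        seq = SequenceRecord("s", random_seq(rng, 120))
        scaled = PWM(matrix_id="x", tf_name="x",
                     weights=3.0 * pu1_pwm.weights + 0.7,
                     background=pu1_pwm.background,
                     pseudocount=pu1_pwm.pseudocount)
        a = scan_pwm(pu1_pwm, seq, threshold=0.5, both_strands=False)
        b = scan_pwm(scaled, seq, threshold=0.5, both_strands=False)
        assert [(h.start, round(h.relative_score, 9)) for h in a] == \
            [(h.start, round(h.relative_score, 9)) for h in b]

    def test_hit_count_monotone_in_threshold(self, pu1_pwm, rng):
        seq = SequenceRecord("s", random_seq(rng, 500))
        counts = [len(scan_pwm(pu1_pwm, seq, threshold=t))
                  for t in (0.5, 0.7, 0.85, 0.95)]
        assert counts == sorted(counts, reverse=True)

    def test_n_scores_as_background(self, pu1_pwm):
        rec = SequenceRecord("s", "NNNNNNNNNN")
        hits = scan_pwm(pu1_pwm, rec, threshold=0.0, both_strands=False)
        rel_of_zero = (0.0 - pu1_pwm.smin) / (pu1_pwm.smax - pu1_pwm.smin)
        assert all(h.relative_score == pytest.approx(rel_of_zero) for h in hits)

    def test_degenerate_pwm_rejected(self):
        pwm = PWM("d", "d", np.zeros((4, 5)), np.full(4, 0.25), 0.8)
        with pytest.raises(ValueError, match="d"):
            scan_pwm(pwm, SequenceRecord("s", "ACGTACGT"), 0.85)

    def test_agrees_with_biopython_pssm(self, tmp_path):
        # independent scorer: biopython's PSSM with the matching
        # pseudocount convention
        from Bio import motifs as bio_motifs

        path = tmp_path / "m.jaspar"
        path.write_text(PU1_JASPAR)
        with open(path) as handle:
            m = bio_motifs.parse(handle, "jaspar")[0]
        pwm_bio = m.counts.normalize(pseudocounts=0.2)
        pssm = pwm_bio.log_odds({b: 0.25 for b in "ACGT"})
        seq = "CACTTCCTTGGAAGTGACCACTTCCTC"
        ours = pfm_to_pwm(read_jaspar(path)[0], pseudocount=0.8)
        raw = np.array(pssm.calculate(seq), dtype=float)
        from firetrace.motifs import _window_scores
        mine = _window_scores(ours, seq)
        assert np.allclose(mine, raw, atol=1e-4)


class TestIupacScan:
    def test_ap1_variant_matches_central_t(self):
        hits = iupac_scan("TGAWTCA", SequenceRecord("s", "CCTGATTCAGG"))
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) == 1 and plus[0].start == 2

    def test_ap1_variant_excludes_classical_site(self):
        assert iupac_scan("TGAWTCA", SequenceRecord("s", "TGAGTCA")) == []

    def test_pu1_core_found_on_minus_strand(self):
        seq = SequenceRecord("s", "AA" + iupac.revcomp("CACTTCCTT") + "AA")
        hits = iupac_scan("CACTTCCYY", seq)
        assert len(hits) == 1
        assert hits[0].strand == "-" and hits[0].start == 2

    def test_fully_degenerate_pattern_saturates(self):
        seq = SequenceRecord("s", "ACGTACGT")
        hits = iupac_scan("NNNN", seq, both_strands=False)
        assert [h.start for h in hits] == list(range(5))

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ValueError, match="position 3"):
            iupac_scan("TGZT", SequenceRecord("s", "ACGT"))


def _hit(seq_id, start, matched, matrix_id="m1", family="AP1"):
    from firetrace.motifs import MotifHit
    return MotifHit(seq_id=seq_id, start=start, strand="+", matrix_id=matrix_id,
                    tf_name=matrix_id, family=family, relative_score=0.9,
                    matched=matched)


class TestGroupByFamily:
    def test_overlapping_same_family_merged(self):
        blocks = group_by_family([_hit("s", 10, "TGACTCA", "fos"),
                                  _hit("s", 13, "TGAGTCA", "jun")])
        assert len(blocks) == 1
        assert (blocks[0].start, blocks[0].end) == (10, 20)

    def test_disjoint_same_family_kept_apart(self):
        blocks = group_by_family([_hit("s", 10, "TGACTCA"),
                                  _hit("s", 40, "TGACTCA")])
        assert len(blocks) == 2

    def test_families_never_merged(self):
        blocks = group_by_family([_hit("s", 10, "TGACTCA", family="AP1"),
                                  _hit("s", 12, "CACTTCC", family="ETS")])
        assert len(blocks) == 2
        assert {b.family for b in blocks} == {"AP1", "ETS"}

    def test_macrophage_flag_from_table(self):
        table = {"fos": ("AP1", True)}
        blocks = group_by_family([_hit("s", 10, "TGACTCA", "fos")], table)
        assert blocks[0].macrophage_expressed


class TestFindCoreElement:
    def test_adjacent_motifs_spacer_zero(self):
        cons = ConsensusSequence(clade="mammal",
                                 seq="GGGG" + "TGATTCA" + "CACTTCCTT" + "GGGG")
        report = find_core_element([cons])
        assert report.core_present
        clade = report.clades[0]
        assert clade.spacer == 0
        assert clade.ap1_pattern == "TGAWTCA"

    def test_snake_arrangement_via_classical_pattern(self):
        cons = ConsensusSequence(clade="snake",
                                 seq="AAAA" + "TGAGTCA" + "GGCCGG" + "CACTTCCCT" + "AAAA")
        report = find_core_element([cons])
        clade = report.clades[0]
        assert clade.present
        assert clade.ap1_pattern == "TGASTCA"
        assert clade.spacer == 6

    def test_missing_ap1_marks_clade_absent(self):
        good = ConsensusSequence(clade="a", seq="TGATTCACACTTCCTT")
        bad = ConsensusSequence(clade="b", seq="GGGGGG" + "CACTTCCTT" + "GGGGGG")
        report = find_core_element([good, bad])
        assert not report.core_present
        verdicts = {c.clade: c.present for c in report.clades}
        assert verdicts == {"a": True, "b": False}

    def test_distant_pair_beyond_max_spacer_absent(self):
        cons = ConsensusSequence(
            clade="c", seq="TGATTCA" + "G" * 40 + "CACTTCCTT")
        report = find_core_element([cons], max_spacer=20)
        assert not report.clades[0].present

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            find_core_element([])
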