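"""Pairwise and progressive multiple alignment, trimming and consensus.

The multiple-alignment stage mirrors the classic progressive strategy:
pairwise distances -> neighbor-joining guide tree -> profile–profile
merges up the tree.  Profiles score columns by the frequency-weighted
expected pair score (ambiguity codes contribute the mean over their base
sets); gap penalties are affine and flat (no position-specific
modifiers, no sequence weighting — this is deliberately not a ClustalW
clone and byte-identical ClustalW output is not promised).

Alignments never edit residues: de-gapping any output row returns the
input sequence verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from firetrace import iupac
from firetrace.extract import ScoringScheme
from firetrace.io import SequenceRecord

GAP = "-"

#: default scoring for global/progressive alignment.  Gap opening is much
#: stiffer than in local database search (where short spurious gaps are
#: pruned by the local-alignment floor): globally homologous ~300 bp
#: elements diverge mostly by substitution, and cheap gap opening lets the
#: profile aligner trade two mismatches for a compensating gap pair,
#: corrupting downstream p-distances.  Same spirit as ClustalW's DNA
#: defaults, where gap opening outweighs a mismatch several-fold.
MSA_SCORING = ScoringScheme(match=2, mismatch=-3, gap_open=-10, gap_extend=-2)

_NEG = -1e30  # effectively -inf, safe for float arithmetic
_TOL = 1e-9


@dataclass
class Alignment:
    """A gapped sequence matrix: ordered (id, gapped sequence) rows."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment needs at least one row")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) != 1:
            raise ValueError("all rows of an alignment must have equal length")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def row(self, i: int) -> str:
        return self.records[i][1]

    def column(self, j: int) -> str:
        return "".join(s[j] for _, s in self.records)

    def degap(self, i: int) -> str:
        return self.records[i][1].replace(GAP, "")


@dataclass
class ConsensusSequence:
    """Per-column consensus of a clade alignment, with call support."""

    clade: str
    seq: str
    support: list[float] = field(default_factory=list)

    def as_record(self) -> SequenceRecord:
        return SequenceRecord(id=f"{self.clade}_consensus" if self.clade else "consensus",
                              seq=self.seq, clade=self.clade)


# ---------------------------------------------------------------------------
# profile representation and the affine-gap DP
# ---------------------------------------------------------------------------

_CODE_FREQ = {}
for _code, _bases in iupac.CODE_TO_BASES.items():
    v = np.zeros(4)
    for _b in _bases:
        v["ACGT".index(_b)] = 1.0 / len(_bases)
    _CODE_FREQ[_code] = v
_CODE_FREQ[GAP] = np.zeros(4)


def _profile_matrix(rows: list[str]) -> np.ndarray:
    """L x 4 base-frequency matrix; gaps contribute a zero vector."""
    length = len(rows[0])
    prof = np.zeros((length, 4))
    for row in rows:
        for j, c in enumerate(row):
            prof[j] += _CODE_FREQ[c]
    return prof / len(rows)


def _substitution_matrix(scoring: ScoringScheme) -> np.ndarray:
    s = np.full((4, 4), float(scoring.mismatch))
    np.fill_diagonal(s, float(scoring.match))
    return s


def _affine_dp(prof_a: np.ndarray, prof_b: np.ndarray,
               scoring: ScoringScheme) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Global affine-gap DP over two profiles.

    Returns (score, M, IA, IB) where M ends in an aligned column, IA in a
    column consuming profile A against a gap (vertical/'up') and IB
    consuming profile B against a gap (horizontal/'left').
    """
    la, lb = len(prof_a), len(prof_b)
    go, ge = float(scoring.gap_open), float(scoring.gap_extend)
    cs = prof_a @ _substitution_matrix(scoring) @ prof_b.T  # L_a x L_b

    M = np.full((la + 1, lb + 1), _NEG)
    IA = np.full((la + 1, lb + 1), _NEG)
    IB = np.full((la + 1, lb + 1), _NEG)
    M[0, 0] = 0.0
    if lb:
        IB[0, 1:] = go + ge * np.arange(lb)
    if la:
        IA[1:, 0] = go + ge * np.arange(la)

    for i in range(1, la + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], IA[i - 1]), IB[i - 1])
        M[i, 1:] = cs[i - 1] + prev_best[:-1]
        IA[i] = np.maximum(np.maximum(M[i - 1], IB[i - 1]) + go, IA[i - 1] + ge)
        # IB within-row recursion: IB[j] = max(P[j-1] + go, IB[j-1] + ge)
        # with P = max(M, IA) of the current row. Closed form over the run of
        # extensions: IB[j] = ge*j + max_{k<j} (P[k] + go - ge*(k+1)).
        P = np.maximum(M[i], IA[i])
        f = P[:-1] + go - ge * (np.arange(lb) + 1)
        run = np.maximum.accumulate(np.maximum(f, IB[i, 0]))
        IB[i, 1:] = ge * (np.arange(lb) + 1) + run
    score = max(M[la, lb], IA[la, lb], IB[la, lb])
    return score, M, IA, IB


def _traceback(M, IA, IB, cs, scoring: ScoringScheme) -> list[str]:
    """Ops from start to end: 'D' aligned, 'U' consumes A, 'L' consumes B.

    Tie-break preference at every choice point: diagonal > up > left.
    """
    go, ge = float(scoring.gap_open), float(scoring.gap_extend)
    i, j = M.shape[0] - 1, M.shape[1] - 1
    vals = (M[i, j], IA[i, j], IB[i, j])
    state = int(np.argmax([v + _TOL * (2 - k) for k, v in enumerate(vals)]))
    # argmax with tiny priority bonus -> prefers M, then IA, then IB on ties
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == 0:  # M: consumed an aligned column
            ops.append("D")
            target = M[i, j] - cs[i - 1, j - 1]
            i, j = i - 1, j - 1
            state = _pick_state(M[i, j], IA[i, j], IB[i, j], target)
        elif state == 1:  # IA: consumed A against a gap ('up')
            ops.append("U")
            val = IA[i, j]
            i -= 1
            if abs(M[i, j] + go - val) < _TOL:
                state = 0
            elif abs(IA[i, j] + ge - val) < _TOL:
                state = 1
            else:
                state = 2
        else:  # IB: consumed B against a gap ('left')
            ops.append("L")
            val = IB[i, j]
            j -= 1
            if abs(M[i, j] + go - val) < _TOL:
                state = 0
            elif abs(IA[i, j] + go - val) < _TOL:
                state = 1
            else:
                state = 2
        if i == 0 and j == 0:
            break
    ops.reverse()
    return ops


def _pick_state(m: float, ia: float, ib: float, target: float) -> int:
    for k, v in enumerate((m, ia, ib)):
        if abs(v - target) < _TOL:
            return k
    # numerical fallback: closest value
    return int(np.argmin([abs(m - target), abs(ia - target), abs(ib - target)]))


def _merge_profiles(rows_a: list[tuple[str, str]], rows_b: list[tuple[str, str]],
                    scoring: ScoringScheme) -> tuple[float, list[tuple[str, str]]]:
    prof_a = _profile_matrix([s for _, s in rows_a])
    prof_b = _profile_matrix([s for _, s in rows_b])
    score, M, IA, IB = _affine_dp(prof_a, prof_b, scoring)
    cs = prof_a @ _substitution_matrix(scoring) @ prof_b.T
    ops = _traceback(M, IA, IB, cs, scoring)
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op == "D":
            for k, (_, s) in enumerate(rows_a):
                out_a[k] += s[ia]
            for k, (_, s) in enumerate(rows_b):
                out_b[k] += s[ib]
            ia += 1
            ib += 1
        elif op == "U":
            for k, (_, s) in enumerate(rows_a):
                out_a[k] += s[ia]
            for k in range(len(rows_b)):
                out_b[k] += GAP
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += GAP
            for k, (_, s) in enumerate(rows_b):
                out_b[k] += s[ib]
            ib += 1
    merged = [(rid, row) for (rid, _), row in zip(rows_a, out_a)]
    merged += [(rid, row) for (rid, _), row in zip(rows_b, out_b)]
    return score, merged


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def global_align_pair(a: SequenceRecord, b: SequenceRecord,
                      scoring: ScoringScheme | None = None) -> Alignment:
    """Optimal Needleman–Wunsch alignment of two sequences (affine gaps)."""
    scoring = scoring or MSA_SCORING
    if not a.seq or not b.seq:
        raise ValueError("cannot align an empty sequence")
    _, merged = _merge_profiles([(a.id, a.seq)], [(b.id, b.seq)], scoring)
    return Alignment(records=merged)


def global_align_score(a: str, b: str, scoring: ScoringScheme | None = None) -> float:
    """Needleman–Wunsch score only (used by tests and guide distances)."""
    scoring = scoring or MSA_SCORING
    score, _, _, _ = _affine_dp(_profile_matrix([a]), _profile_matrix([b]), scoring)
    return float(score)


def _guide_distances(seqs: list[SequenceRecord],
                     scoring: ScoringScheme) -> np.ndarray:
    """Pairwise p-distances from pairwise global alignments."""
    from firetrace.phylogeny import p_distance_pair

    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pair = global_align_pair(seqs[i], seqs[j], scoring)
            diffs, comparable = p_distance_pair(pair.row(0), pair.row(1))
            d[i, j] = d[j, i] = diffs / comparable if comparable else 0.75
    return d


def progressive_msa(seqs: list[SequenceRecord],
                    scoring: ScoringScheme | None = None) -> Alignment:
    """Guide-tree-driven progressive multiple alignment.

    Row order follows input order; the result is deterministic for a
    given input order (guide tree midpoint-rooted, merge-order ties
    broken by the smallest input leaf index in each subtree).
    """
    scoring = scoring or MSA_SCORING
    if len(seqs) < 2:
        raise ValueError(
            "progressive_msa needs at least 2 sequences; "
            "skip alignment for single-sequence clades"
        )
    if len(seqs) == 2:
        return global_align_pair(seqs[0], seqs[1], scoring)

    from skbio import DistanceMatrix as _DM

    from firetrace.phylogeny import neighbor_joining

    index_of = {rec.id: k for k, rec in enumerate(seqs)}
    if len(index_of) != len(seqs):
        raise ValueError("duplicate sequence ids in MSA input")
    d = _guide_distances(seqs, scoring)
    order: list[tuple[list[tuple[str, str]], ...]] = []

    if np.allclose(d, 0.0):
        guide = None  # identical sequences: any merge order gives the same MSA
    else:
        tree = neighbor_joining(_DM(d, ids=[rec.id for rec in seqs]))
        try:
            guide = tree.root_at_midpoint()
        except Exception:
            guide = tree

    if guide is None:
        merged = [(seqs[0].id, seqs[0].seq)]
        for rec in seqs[1:]:
            _, merged = _merge_profiles(merged, [(rec.id, rec.seq)], scoring)
    else:
        merged = _merge_subtree(guide, seqs, index_of, scoring)

    by_input = {rid: row for rid, row in merged}
    return Alignment(records=[(rec.id, by_input[rec.id]) for rec in seqs])


def _merge_subtree(node, seqs, index_of, scoring) -> list[tuple[str, str]]:
    if node.is_tip():
        rec = seqs[index_of[node.name]]
        return [(rec.id, rec.seq)]
    child_profiles = []
    for child in node.children:
        prof = _merge_subtree(child, seqs, index_of, scoring)
        child_profiles.append(prof)
    child_profiles.sort(key=lambda rows: min(index_of[rid] for rid, _ in rows))
    merged = child_profiles[0]
    for prof in child_profiles[1:]:
        _, merged = _merge_profiles(merged, prof, scoring)
    return merged


def sum_of_pairs_score(aln: Alignment, scoring: ScoringScheme | None = None) -> float:
    """Sum over row pairs of match/mismatch/affine-gap scores (sanity metric)."""
    scoring = scoring or MSA_SCORING
    total = 0.0
    n = len(aln.records)
    for i in range(n):
        for j in range(i + 1, n):
            total += _pair_score(aln.row(i), aln.row(j), scoring)
    return total


def _pair_score(a: str, b: str, scoring: ScoringScheme) -> float:
    s = _substitution_matrix(scoring)
    total = 0.0
    gap_a = gap_b = False
    for x, y in zip(a, b):
        if x == GAP and y == GAP:
            continue
        if x == GAP or y == GAP:
            if x == GAP:
                total += scoring.gap_extend if gap_a else scoring.gap_open
                gap_a, gap_b = True, False
            else:
                total += scoring.gap_extend if gap_b else scoring.gap_open
                gap_b, gap_a = True, False
        else:
            total += float(_CODE_FREQ[x] @ s @ _CODE_FREQ[y])
            gap_a = gap_b = False
    return total


def trim_common(aln: Alignment) -> Alignment:
    """Trim to the common-length core.

    Leading and trailing columns containing any gap are removed; interior
    columns are untouched except that all-gap columns are dropped
    everywhere.  Trimming away every column is an error.
    """
    n = len(aln.records)
    cols = [aln.column(j) for j in range(aln.length)]
    start = 0
    while start < len(cols) and GAP in cols[start]:
        start += 1
    end = len(cols)
    while end > start and GAP in cols[end - 1]:
        end -= 1
    kept = [j for j in range(start, end) if cols[j] != GAP * n]
    if not kept:
        raise ValueError("common-length trimming removed every column")
    records = [(rid, "".join(s[j] for j in kept)) for rid, s in aln.records]
    return Alignment(records=records)


def consensus(aln: Alignment, plurality: float = 0.5,
              ambiguity_floor: float = 0.25, clade: str = "",
              max_n_fraction: float = 0.2) -> ConsensusSequence:
    """Per-column consensus with IUPAC ambiguity fallback.

    For each column (among non-gap rows): if the modal base reaches
    *plurality* it is called; otherwise the minimal IUPAC code covering
    every base at frequency >= *ambiguity_floor* is called.  Columns
    with more than 50% gaps are dropped.  Rows whose sequence is more
    than *max_n_fraction* N are excluded up front (heavily N-interrupted
    records, such as draft-genome elements, would only dilute the calls).
    """
    if len(aln.records) < 2:
        raise ValueError("consensus needs at least 2 rows")
    rows = [s for _, s in aln.records]
    usable = [s for s in rows
              if s.count("N") <= max_n_fraction * max(1, len(s) - s.count(GAP))]
    if len(usable) >= 2:
        rows = usable
    n = len(rows)
    out = []
    support = []
    for j in range(len(rows[0])):
        col = [s[j] for s in rows]
        gaps = col.count(GAP)
        if gaps > 0.5 * n:
            continue
        nongap = [c for c in col if c != GAP]
        votes: dict[str, float] = {b: 0.0 for b in "ACGT"}
        for c in nongap:
            for b in iupac.CODE_TO_BASES[c]:
                votes[b] += 1.0 / len(iupac.CODE_TO_BASES[c])
        total = len(nongap)
        freqs = {b: v / total for b, v in votes.items()}
        modal = max(sorted(freqs), key=lambda b: freqs[b])
        if freqs[modal] >= plurality:
            call = modal
        else:
            covered = {b for b, f in freqs.items() if f >= ambiguity_floor}
            if not covered:
                covered = {b for b, f in freqs.items() if f > 0}
            call = iupac.minimal_code(covered)
        matching = sum(1 for c in nongap if iupac.codes_intersect(c, call))
        out.append(call)
        support.append(matching / total)
    return ConsensusSequence(clade=clade, seq="".join(out), support=support)


def percent_identity(aln: Alignment, i: int, j: int) -> float:
    """Fraction of identical sites between rows i and j, pairwise deletion.

    Columns where either row has a gap are skipped; an error is raised
    when no column is comparable.
    """
    a, b = aln.row(i), aln.row(j)
    comparable = matches = 0
    for x, y in zip(a, b):
        if x == GAP or y == GAP:
            continue
        comparable += 1
        if x == y:
            matches += 1
    if comparable == 0:
        raise ValueError(f"rows {i} and {j} share no comparable columns")
    return matches / comparable


def read_aligned_fasta(path) -> Alignment:
    """Read an aligned FASTA (gaps as '-') into an Alignment."""
    from Bio import SeqIO

    records = []
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"{path}: no records")
    return Alignment(records=records)


def write_aligned_fasta(aln: Alignment, path, width: int = 60) -> None:
    with open(path, "w") as handle:
        for rid, seq in aln.records:
            handle.write(f">{rid}\n")
            for k in range(0, len(seq), width):
                handle.write(seq[k:k + width] + "\n")
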