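"""Locating a regulatory element inside larger genomic context.

The ~300 bp element is found by exact local alignment (Smith–Waterman
with affine gaps, both strands) of a known query element against an
intron-scale target, then trimmed to the aligned span so every
extracted element is reported in query orientation.  A primer-based
route (:func:`insilico_pcr`) mirrors the wet-lab amplification used for
species with no assembled genome hit.

The dynamic program itself is Biopython's :class:`PairwiseAligner`
(exact affine-gap DP); this module owns strand handling, coordinate
mapping, identity computation and the not-found rule.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import PairwiseAligner

from firetrace import iupac
from firetrace.io import SequenceRecord

# Best local hits below this identity, or covering fewer aligned columns,
# are reported as "not found" rather than returned: a genuine element hit
# covers most of a ~300 bp query, while the best local alignment between
# unrelated sequences is short.  Mirrors the failure to find the snake
# element by direct sequence search.
DEFAULT_MIN_IDENTITY = 0.55
DEFAULT_MIN_ALIGNED_COLUMNS = 100


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring: a gap of length L costs gap_open + (L-1)*gap_extend."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("require gap_open <= gap_extend <= 0")


@dataclass(frozen=True)
class LocalHit:
    """A local alignment of the query element against a target.

    Spans are 0-based half-open on the forward strand of each sequence;
    ``strand == '-'`` means the query matched the reverse complement of
    the target span.  ``aligned_identity`` is matches over alignment
    columns (gap columns included in the denominator).
    """

    target_id: str
    target_span: tuple[int, int]
    query_span: tuple[int, int]
    strand: str
    score: float
    aligned_identity: float


def _make_aligner(scoring: ScoringScheme, mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _alignment_stats(alignment) -> tuple[int, int, tuple[int, int], tuple[int, int]]:
    """(matches, columns, query_span, target_span) of a biopython alignment."""
    qaln, taln = alignment.aligned  # blocks: [[qs,qe],...], [[ts,te],...]
    q, t = alignment.sequences
    matches = 0
    aligned_cols = 0
    for (qs, qe), (ts, te) in zip(qaln, taln):
        aligned_cols += qe - qs
        matches += sum(1 for a, b in zip(q[qs:qe], t[ts:te]) if a == b)
    qspan = (int(qaln[0][0]), int(qaln[-1][1]))
    tspan = (int(taln[0][0]), int(taln[-1][1]))
    # gap columns inside the local region
    gap_cols = (qspan[1] - qspan[0] - aligned_cols) + (tspan[1] - tspan[0] - aligned_cols)
    return matches, aligned_cols + gap_cols, qspan, tspan


def _best_local(query: str, target: str, scoring: ScoringScheme):
    """Best-scoring local alignment; smallest target start among the first ties."""
    aligner = _make_aligner(scoring, "local")
    alignments = aligner.align(query, target)
    if not alignments:
        return None
    try:
        n = min(len(alignments), 64)
    except OverflowError:  # astronomically many co-optimal tracebacks
        n = 64
    best = min(
        (alignments[i] for i in range(n)),
        key=lambda a: int(a.aligned[1][0][0]),
    )
    return best


def local_align(query: str, target: str, scoring: ScoringScheme | None = None):
    """Single-strand Smith–Waterman. Returns (score, matches, columns, qspan, tspan)."""
    scoring = scoring or ScoringScheme()
    best = _best_local(query, target, scoring)
    if best is None or best.score <= 0:
        return None
    matches, columns, qspan, tspan = _alignment_stats(best)
    return best.score, matches, columns, qspan, tspan


def locate_element(
    query: SequenceRecord,
    target: SequenceRecord,
    scoring: ScoringScheme | None = None,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_aligned_columns: int = DEFAULT_MIN_ALIGNED_COLUMNS,
) -> LocalHit | None:
    """Find the best local hit of *query* in *target*, searching both strands.

    Returns ``None`` ("not found", distinct from an error) when the best
    hit falls below *min_identity* over *min_aligned_columns* columns.
    Ties between strands break toward '+'.
    """
    scoring = scoring or ScoringScheme()
    if len(query) < 20:
        raise ValueError("query shorter than 20 nt cannot anchor a search")
    if len(target) < len(query):
        raise ValueError("target shorter than query")

    candidates = []
    for strand, tseq in (("+", target.seq), ("-", iupac.revcomp(target.seq))):
        res = local_align(query.seq, tseq, scoring)
        if res is None:
            continue
        score, matches, columns, qspan, tspan = res
        if strand == "-":
            tspan = (len(target) - tspan[1], len(target) - tspan[0])
        candidates.append(
            LocalHit(
                target_id=target.id,
                target_span=tspan,
                query_span=qspan,
                strand=strand,
                score=score,
                aligned_identity=matches / columns if columns else 0.0,
            )
        )
    if not candidates:
        return None
    # highest score; ties -> smallest target start, then '+' strand
    best = min(candidates, key=lambda h: (-h.score, h.target_span[0], h.strand))
    columns = best.target_span[1] - best.target_span[0]
    if best.aligned_identity < min_identity or columns < min_aligned_columns:
        return None
    return best


def trim_to_query(hit: LocalHit, target: SequenceRecord) -> SequenceRecord:
    """Extract the target subsequence under *hit*, in query orientation."""
    start, end = hit.target_span
    if not (0 <= start < end <= len(target)):
        raise ValueError(f"hit span {hit.target_span} outside target bounds")
    seq = target.seq[start:end]
    if hit.strand == "-":
        seq = iupac.revcomp(seq)
    return SequenceRecord(
        id=f"{target.id}_element",
        seq=seq,
        clade=target.clade,
        source_note=f"extracted {start + 1}-{end} ({hit.strand}) from {target.id}",
    )


def _primer_sites(primer: str, template: str, max_mismatches: int,
                  anchor_3prime: str) -> list[int]:
    """Start positions where *primer* anneals to the + strand of *template*.

    ``anchor_3prime`` is 'right' for a forward primer (its 3' terminus is
    the rightmost base of the site) and 'left' for the reverse-complemented
    reverse primer (3' terminus leftmost).  The 3'-terminal 3 bases must
    match exactly; elsewhere up to *max_mismatches* mismatches are allowed
    (IUPAC codes match when base sets intersect).
    """
    L = len(primer)
    sites = []
    for start in range(len(template) - L + 1):
        window = template[start:start + L]
        mism = [i for i in range(L)
                if not iupac.codes_intersect(primer[i], window[i])]
        if len(mism) > max_mismatches:
            continue
        anchor = range(L - 3, L) if anchor_3prime == "right" else range(3)
        if any(i in anchor for i in mism):
            continue
        sites.append(start)
    return sites


def insilico_pcr(
    fwd_primer: str,
    rev_primer: str,
    target: SequenceRecord,
    max_mismatches: int = 0,
    max_product: int = 2000,
) -> list[SequenceRecord]:
    """Predict PCR products of a primer pair on *target*.

    The forward primer must match the + strand and the reverse primer's
    reverse complement must match downstream on the + strand, within
    *max_product*; each primer tolerates at most *max_mismatches*
    mismatches with its 3'-terminal 3 bases exact.  Products include
    both primer sites and are reported 5'->3' by start position.
    """
    fwd = fwd_primer.upper()
    rev = rev_primer.upper()
    if len(fwd) < 15 or len(rev) < 15:
        raise ValueError("primers must be at least 15 nt")
    template = target.seq
    rev_rc = iupac.revcomp(rev)
    fwd_sites = _primer_sites(fwd, template, max_mismatches, "right")
    rev_sites = _primer_sites(rev_rc, template, max_mismatches, "left")
    amplicons = []
    for fs in fwd_sites:
        for rs in rev_sites:
            end = rs + len(rev_rc)
            if rs < fs + len(fwd):
                continue  # reverse site must lie downstream of the forward site
            if end - fs > max_product:
                continue
            amplicons.append(
                SequenceRecord(
                    id=f"{target.id}_amplicon_{fs + 1}_{end}",
                    seq=template[fs:end],
                    clade=target.clade,
                    source_note=f"in-silico PCR product {fs + 1}-{end} of {target.id}",
                )
            )
    amplicons.sort(key=lambda r: r.id)
    amplicons.sort(key=lambda r: int(r.id.rsplit("_", 2)[-2]))
    return amplicons
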