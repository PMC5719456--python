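"""PWM and degenerate-pattern motif annotation.

Position frequency matrices (JASPAR text format) are converted to
log-odds position weight matrices and scanned at a *relative score*
threshold: ``(S - Smin) / (Smax - Smin)`` where ``Smax``/``Smin`` are
the best and worst achievable sums — the standard "% match to the
matrix" scale on which an 85% cutoff is defined.  Hits from
transcription-factor family members are grouped into family blocks,
and :func:`find_core_element` looks for the conserved arrangement this
package exists to detect: an AP1 site (``TGAWTCA``, or the classical
``TGASTCA``) next to the PU.1/ETS core ``CACTTCCYY`` within a short
spacer, in every clade consensus.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np
from Bio import motifs as _bio_motifs

from firetrace import iupac
from firetrace.io import SequenceRecord

_BASES = "ACGT"

AP1_VARIANT = "TGAWTCA"   # central A/T, the arrangement conserved lizard->human
AP1_CLASSICAL = "TGASTCA"  # classical Fos/Jun consensus (snake form TGAGTCA)
PU1_CORE = "CACTTCCYY"     # high-affinity PU.1/ETS site (RRGGAAGTG on the - strand)


@dataclass
class PFM:
    """A position frequency matrix: base counts per motif column."""

    matrix_id: str
    tf_name: str
    counts: np.ndarray  # 4 x L, rows A, C, G, T
    family: str = "other"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4:
            raise ValueError(f"{self.matrix_id}: counts must have 4 rows (A,C,G,T)")
        if self.counts.shape[1] < 4:
            raise ValueError(f"{self.matrix_id}: motif shorter than 4 columns")
        if (self.counts < 0).any():
            raise ValueError(f"{self.matrix_id}: negative counts")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError(f"{self.matrix_id}: zero column sum")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.counts.argmax(axis=0))


@dataclass
class PWM:
    """Log-odds weights derived from a PFM against a background."""

    matrix_id: str
    tf_name: str
    weights: np.ndarray  # 4 x L
    background: np.ndarray
    pseudocount: float
    family: str = "other"

    @property
    def length(self) -> int:
        return self.weights.shape[1]

    @property
    def smax(self) -> float:
        return float(self.weights.max(axis=0).sum())

    @property
    def smin(self) -> float:
        return float(self.weights.min(axis=0).sum())


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; start is 0-based on the forward strand."""

    seq_id: str
    start: int
    strand: str
    matrix_id: str
    tf_name: str
    family: str
    relative_score: float
    matched: str

    @property
    def end(self) -> int:
        return self.start + len(self.matched)


def read_jaspar(path, family_table: dict[str, tuple[str, bool]] | None = None) -> list[PFM]:
    """Read JASPAR-format PFMs (">ID NAME" then bracketed A/C/G/T count rows).

    *family_table* maps matrix_id -> (family, macrophage_expressed); ids
    without a mapping get family "other".
    """
    with open(path) as handle:
        try:
            parsed = _bio_motifs.parse(handle, "jaspar")
        except Exception as exc:
            raise ValueError(f"{path}: JASPAR parse error: {exc}") from exc
    pfms = []
    for m in parsed:
        counts = np.array([list(m.counts[b]) for b in _BASES], dtype=float)
        family = "other"
        if family_table and m.matrix_id in family_table:
            family = family_table[m.matrix_id][0]
        pfms.append(PFM(matrix_id=m.matrix_id or m.name, tf_name=m.name,
                        counts=counts, family=family))
    if not pfms:
        raise ValueError(f"{path}: no matrices found")
    return pfms


def read_family_table(path) -> dict[str, tuple[str, bool]]:
    """TSV with columns matrix_id, family, macrophage_expressed (yes/no)."""
    table: dict[str, tuple[str, bool]] = {}
    with open(path) as handle:
        reader = csv.reader(handle, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            mid, fam = row[0], row[1]
            expressed = len(row) > 2 and row[2].strip().lower() in ("yes", "true", "1")
            table[mid] = (fam, expressed)
    return table


def pfm_to_pwm(pfm: PFM, pseudocount: float = 0.8,
               background: np.ndarray | None = None) -> PWM:
    """Log-odds PWM: w(b,i) = log2((n(b,i) + pc*bg(b)) / (N(i) + pc) / bg(b)).

    The pseudocount is split across bases in proportion to the
    background (the JASPAR/MOODS convention); default background is
    uniform.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-6) or (bg <= 0).any():
        raise ValueError("background must be 4 positive frequencies summing to 1")
    colsum = pfm.counts.sum(axis=0)
    probs = (pfm.counts + pseudocount * bg[:, None]) / (colsum + pseudocount)
    weights = np.log2(probs / bg[:, None])
    return PWM(matrix_id=pfm.matrix_id, tf_name=pfm.tf_name, weights=weights,
               background=bg, pseudocount=pseudocount, family=pfm.family)


def _window_scores(pwm: PWM, seq: str) -> np.ndarray:
    """PWM sum at every window start; ambiguity codes score the mean over
    their base set, N (and any full-ambiguity code) therefore scores the
    plain average weight — background-like, near zero."""
    L = pwm.length
    n = len(seq)
    if n < L:
        return np.zeros(0)
    col_cache: dict[str, np.ndarray] = {}
    for c in set(seq):
        if c == "N":
            col_cache[c] = np.zeros(L)  # background-like: zero contribution
            continue
        bases = iupac.CODE_TO_BASES[c]
        idx = [_BASES.index(b) for b in bases]
        col_cache[c] = pwm.weights[idx, :].mean(axis=0)  # length-L vector
    scores = np.zeros(n - L + 1)
    for offset in range(L):
        col = np.array([col_cache[seq[offset + s]][offset] for s in range(n - L + 1)])
        scores += col
    return scores


def scan_pwm(pwm: PWM, seq: SequenceRecord, threshold: float = 0.85,
             both_strands: bool = True) -> list[MotifHit]:
    """All windows whose relative score reaches *threshold*.

    Hits are sorted by forward-strand position, '+' before '-' at the
    same position.  A PWM whose best and worst achievable scores
    coincide cannot be scanned and is an error.
    """
    if len(seq) < pwm.length:
        raise ValueError(f"sequence {seq.id!r} shorter than motif {pwm.matrix_id}")
    smax, smin = pwm.smax, pwm.smin
    if math.isclose(smax, smin):
        raise ValueError(f"degenerate PWM {pwm.matrix_id}: Smax equals Smin")
    hits = []
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        s = seq.seq if strand == "+" else iupac.revcomp(seq.seq)
        scores = _window_scores(pwm, s)
        rel = (scores - smin) / (smax - smin)
        for pos in np.nonzero(rel >= threshold - 1e-12)[0]:
            pos = int(pos)
            if strand == "+":
                start = pos
                matched = seq.seq[start:start + pwm.length]
            else:
                start = len(seq) - pos - pwm.length
                matched = seq.seq[start:start + pwm.length]
            hits.append(MotifHit(seq_id=seq.id, start=start, strand=strand,
                                 matrix_id=pwm.matrix_id, tf_name=pwm.tf_name,
                                 family=pwm.family,
                                 relative_score=float(rel[pos]), matched=matched))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def iupac_scan(pattern: str, seq: SequenceRecord,
               both_strands: bool = True) -> list[MotifHit]:
    """Exact degenerate matching of an IUPAC pattern, one hit per occurrence.

    A sequence position matches a pattern position when their base sets
    intersect (so a consensus Y matches a pattern W only if they share a
    base — here they share T).
    """
    pattern = pattern.upper()
    bad = iupac.first_invalid(pattern)
    if bad is not None:
        raise ValueError(f"invalid IUPAC code in pattern at position {bad + 1}")
    hits = []
    strands = ["+", "-"] if both_strands else ["+"]
    L = len(pattern)
    for strand in strands:
        s = seq.seq if strand == "+" else iupac.revcomp(seq.seq)
        for pos in range(len(s) - L + 1):
            window = s[pos:pos + L]
            if all(iupac.codes_intersect(p, c) for p, c in zip(pattern, window)):
                start = pos if strand == "+" else len(seq) - pos - L
                hits.append(MotifHit(seq_id=seq.id, start=start, strand=strand,
                                     matrix_id=f"iupac:{pattern}", tf_name=pattern,
                                     family="pattern", relative_score=1.0,
                                     matched=seq.seq[start:start + L]))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


@dataclass
class FamilyBlock:
    """Union of overlapping same-family hits on one sequence."""

    seq_id: str
    family: str
    start: int
    end: int
    hits: list[MotifHit] = field(default_factory=list)
    macrophage_expressed: bool = False


def group_by_family(hits: list[MotifHit],
                    family_table: dict[str, tuple[str, bool]] | None = None
                    ) -> list[FamilyBlock]:
    """Merge overlapping hits of the same family into annotation blocks.

    Families are never merged with each other; the macrophage-expressed
    flag is carried from the table when any member matrix is flagged.
    """
    family_table = family_table or {}

    def fam_of(h: MotifHit) -> str:
        if h.matrix_id in family_table:
            return family_table[h.matrix_id][0]
        return h.family or "other"

    blocks: list[FamilyBlock] = []
    keyed: dict[tuple[str, str], list[MotifHit]] = {}
    for h in hits:
        keyed.setdefault((h.seq_id, fam_of(h)), []).append(h)
    for (seq_id, family), fam_hits in sorted(keyed.items()):
        fam_hits.sort(key=lambda h: h.start)
        current: FamilyBlock | None = None
        for h in fam_hits:
            expressed = family_table.get(h.matrix_id, ("", False))[1]
            if current is not None and h.start < current.end:
                current.end = max(current.end, h.end)
                current.hits.append(h)
                current.macrophage_expressed |= expressed
            else:
                current = FamilyBlock(seq_id=seq_id, family=family,
                                      start=h.start, end=h.end, hits=[h],
                                      macrophage_expressed=expressed)
                blocks.append(current)
    blocks.sort(key=lambda b: (b.seq_id, b.start, b.family))
    return blocks


@dataclass
class CladeCore:
    """AP1/PU.1 arrangement found (or not) in one clade consensus."""

    clade: str
    present: bool
    ap1: MotifHit | None = None
    pu1: MotifHit | None = None
    ap1_pattern: str | None = None
    spacer: int | None = None
    orientation: str | None = None  # 'same' or 'opposite' strand

    def to_dict(self) -> dict:
        d = {"clade": self.clade, "present": self.present}
        if self.present:
            assert self.ap1 is not None and self.pu1 is not None
            d.update({
                "ap1_pattern": self.ap1_pattern,
                "ap1_start": self.ap1.start, "ap1_strand": self.ap1.strand,
                "ap1_matched": self.ap1.matched,
                "pu1_start": self.pu1.start, "pu1_strand": self.pu1.strand,
                "pu1_matched": self.pu1.matched,
                "spacer": self.spacer, "orientation": self.orientation,
            })
        return d


@dataclass
class CoreElementReport:
    """Cross-clade verdict on the conserved AP1/PU.1 core."""

    clades: list[CladeCore]
    core_present: bool

    def to_dict(self) -> dict:
        return {"core_present": self.core_present,
                "clades": [c.to_dict() for c in self.clades]}


def find_core_element(consensi, ap1_patterns: tuple[str, ...] = (AP1_VARIANT, AP1_CLASSICAL),
                      pu1_pattern: str = PU1_CORE,
                      max_spacer: int = 20) -> CoreElementReport:
    """Detect the conserved AP1/PU.1 core across clade consensi.

    For each consensus, the nearest AP1/PU.1 hit pair with a spacer (end
    of the upstream motif to start of the downstream one) within
    *max_spacer* is reported; AP1 patterns are tried in order so the
    conserved variant (central A/T) is preferred over the classical
    consensus when both match.  The overall verdict is present only when
    every clade has the pair.
    """
    if not consensi:
        raise ValueError("need at least one consensus sequence")
    clades = []
    for cons in consensi:
        rec = cons.as_record() if hasattr(cons, "as_record") else cons
        clade = getattr(cons, "clade", "") or rec.clade or rec.id
        pu1_hits = iupac_scan(pu1_pattern, rec)
        found: CladeCore | None = None
        for pattern in ap1_patterns:
            ap1_hits = iupac_scan(pattern, rec)
            best = _nearest_pair(ap1_hits, pu1_hits, max_spacer)
            if best is not None:
                ap1, pu1, spacer = best
                found = CladeCore(
                    clade=clade, present=True, ap1=ap1, pu1=pu1,
                    ap1_pattern=pattern, spacer=spacer,
                    orientation="same" if ap1.strand == pu1.strand else "opposite",
                )
                break
        clades.append(found or CladeCore(clade=clade, present=False))
    return CoreElementReport(clades=clades,
                             core_present=all(c.present for c in clades))


def _nearest_pair(ap1_hits, pu1_hits, max_spacer):
    best = None
    for a in ap1_hits:
        for p in pu1_hits:
            upstream, downstream = (a, p) if a.start <= p.start else (p, a)
            spacer = max(0, downstream.start - upstream.end)
            if spacer > max_spacer:
                continue
            if best is None or spacer < best[2]:
                best = (a, p, spacer)
    return best


def write_hits_bed(hits: list[MotifHit], path) -> None:
    """BED6+ motif hits: seq, start, end, matrix_id, 1000*rel_score, strand, name, family."""
    with open(path, "w") as handle:
        for h in hits:
            handle.write(
                f"{h.seq_id}\t{h.start}\t{h.end}\t{h.matrix_id}\t"
                f"{round(1000 * h.relative_score)}\t{h.strand}\t"
                f"{h.tf_name}\t{h.family}\n"
            )
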