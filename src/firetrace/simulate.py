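"""Synthetic evolution of enhancer-like elements along a known tree.

The generator emulates the statistical structure the analysis assumes a
conserved non-exonic element to have: a ~300 bp element descending from
a common ancestor along a known tree, carrying

* a strongly constrained core block (the AP1/PU.1 site pair) whose
  substitution rate is multiplied by ~0,
* clade-private moderately constrained motif blocks (candidate
  transcription-factor sites), and
* unconstrained spacer drifting by Jukes–Cantor substitutions and
  small geometric-length indels (indels never touch constrained
  blocks).

Branch lengths are expected substitutions per site at unconstrained
sites.  The indel rate is expected indel events per site per unit
branch length, so indels co-scale with substitutions.  A single global
seed fans out into independent per-branch streams keyed by a
deterministic branch index, so any subtree of a dataset is reproducible
on its own.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from firetrace.io import SequenceRecord
from firetrace.phylogeny import read_newick, write_newick

_BASES = "ACGT"


@dataclass(frozen=True)
class MotifBlock:
    """A planted motif: offset in the element, IUPAC string, and a
    substitution-rate multiplier in [0, 1] (0 = frozen, 1 = neutral)."""

    offset: int
    motif: str
    constraint: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.constraint <= 1.0):
            raise ValueError("constraint multiplier must be in [0, 1]")
        if self.offset < 0:
            raise ValueError("block offset must be non-negative")

    @property
    def length(self) -> int:
        return len(self.motif)


@dataclass
class ElementArchitecture:
    """Layout of one element: length, motif blocks, background GC."""

    length: int = 300
    motif_blocks: list[MotifBlock] = field(default_factory=list)
    gc: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc <= 1.0):
            raise ValueError("GC fraction must be in [0, 1]")
        spans = sorted((b.offset, b.offset + b.length) for b in self.motif_blocks)
        for (s, e) in spans:
            if e > self.length:
                raise ValueError("motif block extends past the element")
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("motif blocks overlap")


@dataclass
class SimTruth:
    """Planted ground truth of one simulated clade."""

    tree_newick: str
    motif_coords: dict[str, list[tuple[int, int, str]]]  # leaf -> (start, end, motif)
    seed: int

    def to_dict(self) -> dict:
        return {
            "tree": self.tree_newick,
            "motif_coords": {k: [list(t) for t in v]
                             for k, v in self.motif_coords.items()},
            "seed": self.seed,
        }

    def write(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(self.to_dict(), handle, indent=2)


def sample_root(arch: ElementArchitecture, rng_seed: int) -> SequenceRecord:
    """Draw a root element: i.i.d. background at the given GC, with each
    motif block instantiated by sampling one concrete base per IUPAC code."""
    from firetrace import iupac

    rng = np.random.default_rng(rng_seed)
    p = np.array([(1 - arch.gc) / 2, arch.gc / 2, arch.gc / 2, (1 - arch.gc) / 2])
    seq = list(rng.choice(list(_BASES), size=arch.length, p=p))
    for block in arch.motif_blocks:
        for i, code in enumerate(block.motif.upper()):
            choices = sorted(iupac.CODE_TO_BASES[code])
            seq[block.offset + i] = choices[int(rng.integers(len(choices)))]
    return SequenceRecord(id="root", seq="".join(seq))


def _site_multipliers(length: int, blocks: list[tuple[int, int, float, str]]) -> np.ndarray:
    mult = np.ones(length)
    for start, end, constraint, _ in blocks:
        mult[start:end] = constraint
    return mult


def _evolve_branch(seq: list[str], blocks: list[tuple[int, int, float, str]],
                   t: float, indel_rate: float, rng: np.random.Generator
                   ) -> tuple[list[str], list[tuple[int, int, float, str]]]:
    if t < 0:
        raise ValueError("branch length must be non-negative")
    seq = list(seq)
    blocks = list(blocks)

    # Jukes–Cantor substitutions, per-site rate scaled by the block multiplier
    mult = _site_multipliers(len(seq), blocks)
    p_change = 0.75 * (1.0 - np.exp(-4.0 * t * mult / 3.0))
    hit = rng.random(len(seq)) < p_change
    for i in np.nonzero(hit)[0]:
        base = seq[i]
        if base not in _BASES:
            continue  # ambiguity/N sites are left untouched
        others = [b for b in _BASES if b != base]
        seq[i] = others[int(rng.integers(3))]

    # indels in unconstrained regions only
    n_events = int(rng.poisson(indel_rate * len(seq) * t)) if indel_rate > 0 else 0
    for _ in range(n_events):
        unconstrained = np.nonzero(_site_multipliers(len(seq), blocks) == 1.0)[0]
        if len(unconstrained) == 0:
            break
        size = int(rng.geometric(0.5))
        pos = int(unconstrained[int(rng.integers(len(unconstrained)))])
        if rng.random() < 0.5:
            # deletion: remove up to `size` unconstrained sites starting at pos
            end = pos
            while end < len(seq) and end - pos < size and \
                    all(not (s <= end < e) for s, e, _, _ in blocks):
                end += 1
            if end == pos:
                continue
            del seq[pos:end]
            removed = end - pos
            blocks = [(s - removed if s >= end else s,
                       e - removed if s >= end else e, c, m)
                      for s, e, c, m in blocks]
        else:
            insert = [_BASES[int(rng.integers(4))] for _ in range(size)]
            seq[pos:pos] = insert
            blocks = [(s + size if s >= pos else s,
                       e + size if s >= pos else e, c, m)
                      for s, e, c, m in blocks]
    return seq, blocks


def evolve_tree(root: SequenceRecord, tree: TreeNode | str,
                arch: ElementArchitecture, indel_rate: float = 0.0,
                rng_seed: int = 0) -> tuple[list[SequenceRecord], SimTruth]:
    """Evolve *root* down *tree*; returns leaf records and planted truth.

    Branch lengths are expected substitutions/site (unconstrained
    sites); every branch draws from its own RNG stream derived from
    ``(rng_seed, branch_index)`` with branch indices assigned in
    preorder, so results are reproducible piecewise.
    """
    if indel_rate < 0:
        raise ValueError("indel_rate must be non-negative")
    if isinstance(tree, str):
        tree = read_newick(tree)
    for node in tree.traverse(include_self=False):
        if node.length is None or node.length < 0:
            raise ValueError("every branch needs a non-negative length")

    blocks0 = [(b.offset, b.offset + b.length, b.constraint, b.motif)
               for b in arch.motif_blocks]
    leaves: list[SequenceRecord] = []
    coords: dict[str, list[tuple[int, int, str]]] = {}

    counter = {"i": 0}

    def walk(node, seq, blocks):
        for child in node.children:
            counter["i"] += 1
            rng = np.random.default_rng([rng_seed, counter["i"]])
            cseq, cblocks = _evolve_branch(seq, blocks, child.length,
                                           indel_rate, rng)
            if child.is_tip():
                name = child.name or f"leaf{counter['i']}"
                leaves.append(SequenceRecord(id=name, seq="".join(cseq)))
                coords[name] = [(s, e, m) for s, e, _, m in cblocks]
            else:
                walk(child, cseq, cblocks)

    walk(tree, list(root.seq), blocks0)
    return leaves, SimTruth(tree_newick=write_newick(tree).strip(),
                            motif_coords=coords, seed=rng_seed)


def random_tree(n_leaves: int, rng_seed: int, branch_length: float = 0.08,
                jitter: float = 0.5, prefix: str = "t") -> TreeNode:
    """A random rooted binary tree with branch lengths around *branch_length*.

    Lengths are drawn uniformly from ``branch_length * [1-jitter, 1+jitter]``.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(rng_seed)

    def bl() -> float:
        return float(branch_length * (1 + jitter * (2 * rng.random() - 1)))

    nodes = [TreeNode(name=f"{prefix}{i + 1}") for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length, b.length = bl(), bl()
        parent = TreeNode(children=[a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    return nodes[0]


# ---------------------------------------------------------------------------
# the default three-clade study: a shared AP1/PU.1 core with clade-private
# motif blocks, one clade carrying the snake-like displaced classical AP1
# ---------------------------------------------------------------------------

#: conserved core: AP1 variant (central A/T) immediately apposed to the
#: PU.1 site — offsets relative to the core placement in each clade
SHARED_CORE = (MotifBlock(0, "TGAWTCA", 0.0), MotifBlock(7, "CACTTCCYY", 0.0))

#: snake-like core: classical AP1 displaced 6 bp from the PU.1 site
SNAKE_CORE = (MotifBlock(0, "TGAGTCA", 0.0), MotifBlock(13, "CACTTCCYY", 0.0))


@dataclass
class CladeSpec:
    """One clade of a synthetic dataset."""

    name: str
    tree: TreeNode
    core_offset: int
    core: tuple[MotifBlock, ...] = SHARED_CORE
    private_blocks: tuple[MotifBlock, ...] = ()  # absolute offsets
    length: int = 300
    gc: float = 0.5


def default_study_specs(n_leaves: int = 6, branch_length: float = 0.08,
                        rng_seed: int = 0) -> list[CladeSpec]:
    """Three clades around a shared core, one with the snake arrangement.

    Private moderately constrained blocks (multiplier 0.2) stand in for
    clade-specific candidate transcription-factor sites; motifs are
    macrophage-factor consensi (CEBP, RUNX, KLF, IRF-like).
    """
    return [
        CladeSpec(name="mammal",
                  tree=random_tree(n_leaves, rng_seed * 7 + 1, branch_length, prefix="mam"),
                  core_offset=140,
                  private_blocks=(MotifBlock(40, "TTGCGCAA", 0.2),    # CEBP
                                  MotifBlock(200, "TGTGGTTT", 0.2))),  # RUNX
        CladeSpec(name="avian",
                  tree=random_tree(n_leaves, rng_seed * 7 + 2, branch_length, prefix="avi"),
                  core_offset=120,
                  private_blocks=(MotifBlock(60, "GGGGAGGGG", 0.2),   # KLF
                                  MotifBlock(220, "TTTCACTTTC", 0.2))),  # IRF-like
        CladeSpec(name="snake",
                  tree=random_tree(n_leaves, rng_seed * 7 + 3, branch_length, prefix="snk"),
                  core_offset=150,
                  core=SNAKE_CORE,
                  private_blocks=(MotifBlock(50, "TTGCGCAA", 0.2),)),
    ]


def make_clade_dataset(specs: list[CladeSpec], indel_rate: float = 0.005,
                       rng_seed: int = 0, outdir=None
                       ) -> tuple[dict[str, list[SequenceRecord]], dict[str, SimTruth]]:
    """Simulate one FASTA-worth of sequences per clade, plus planted truth.

    Each clade descends from its own sampled root; the shared core
    blocks are planted in every clade at that clade's ``core_offset``.
    When *outdir* is given, per-clade FASTA files and a ``truth.json``
    are written there.
    """
    datasets: dict[str, list[SequenceRecord]] = {}
    truths: dict[str, SimTruth] = {}
    for k, spec in enumerate(specs):
        blocks = [MotifBlock(spec.core_offset + b.offset, b.motif, b.constraint)
                  for b in spec.core]
        blocks += list(spec.private_blocks)
        arch = ElementArchitecture(length=spec.length, motif_blocks=blocks,
                                   gc=spec.gc)
        clade_seed = rng_seed * 1009 + 17 * k + 1
        root = sample_root(arch, clade_seed)
        leaves, truth = evolve_tree(root, spec.tree, arch,
                                    indel_rate=indel_rate, rng_seed=clade_seed)
        datasets[spec.name] = [rec.with_clade(spec.name) for rec in leaves]
        truths[spec.name] = truth
    if outdir is not None:
        import os

        from firetrace.io import write_fasta

        os.makedirs(outdir, exist_ok=True)
        for name, records in datasets.items():
            write_fasta(records, os.path.join(outdir, f"{name}.fa"))
        with open(os.path.join(outdir, "truth.json"), "w") as handle:
            json.dump({name: t.to_dict() for name, t in truths.items()},
                      handle, indent=2)
    return datasets, truths
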