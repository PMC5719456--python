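#!/usr/bin/env python
"""Cross-clade dot-matrix comparison of the clade consensi.

Compares every pair of clade consensus sequences with a 15 bp window at
70% minimum identity (both strands).  With clade-private motif blocks
and independently drawn backgrounds, alignable segments between clades
should be confined to the shared AP1/PU.1 core; within the
mammal/avian pair the core segment is the diagnostic diagonal.  Writes
one BED-like segment table per pair under results/dotplots/.
"""

import argparse
import itertools
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from firetrace.dotmatrix import DotMatrixParams, dot_matrix, write_segments_tsv
from firetrace.io import read_fasta


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--clades", default="results/clades")
    ap.add_argument("--out", default="results/dotplots")
    ap.add_argument("--window", type=int, default=15)
    ap.add_argument("--min-identity", type=float, default=0.70)
    args = ap.parse_args()

    clade_dir = pathlib.Path(args.clades)
    out = pathlib.Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    params = DotMatrixParams(window=args.window, min_identity=args.min_identity)

    consensi = {p.name.split(".")[0]: read_fasta(p)[0]
                for p in sorted(clade_dir.glob("*.consensus.fa"))}
    for a, b in itertools.combinations(sorted(consensi), 2):
        segments = dot_matrix(consensi[a], consensi[b], params)
        path = out / f"{a}_vs_{b}.tsv"
        write_segments_tsv(segments, a, b, path)
        longest = max((s.length for s in segments), default=0)
        print(f"{a} vs {b}: {len(segments)} segment(s), longest {longest} bp")
    print(f"wrote segment tables to {out}")


if __name__ == "__main__":
    main()
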