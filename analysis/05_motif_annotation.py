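#!/usr/bin/env python
"""Motif annotation of the clade consensi and the cross-clade core report.

Scans each clade consensus with the bundled synthetic PFMs (PU.1/ETS,
AP1, CEBP, RUNX, KLF consensus-shaped matrices) at a relative-score
threshold of 0.85, groups overlapping hits of one family into blocks,
and then searches for the conserved core: an AP1 site (TGAWTCA, falling
back to the classical TGASTCA) within 20 bp of the PU.1 site CACTTCCYY
in every clade.  Writes motif_hits.bed, family_blocks.tsv and
core_element.json under results/motifs/.
"""

import argparse
import json
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from firetrace.align import ConsensusSequence
from firetrace.io import read_fasta
from firetrace.motifs import (find_core_element, group_by_family, pfm_to_pwm,
                              read_family_table, read_jaspar, scan_pwm,
                              write_hits_bed)

REPO = pathlib.Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--clades", default="results/clades")
    ap.add_argument("--out", default="results/motifs")
    ap.add_argument("--pfm", default=str(REPO / "data/synthetic_tf_motifs.jaspar"))
    ap.add_argument("--families", default=str(REPO / "data/tf_families.tsv"))
    ap.add_argument("--threshold", type=float, default=0.85)
    args = ap.parse_args()

    out = pathlib.Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    table = read_family_table(args.families)
    pwms = [pfm_to_pwm(p) for p in read_jaspar(args.pfm, table)]

    consensi = []
    hits = []
    for path in sorted(pathlib.Path(args.clades).glob("*.consensus.fa")):
        rec = read_fasta(path)[0]
        clade = path.name.split(".")[0]
        consensi.append(ConsensusSequence(clade=clade, seq=rec.seq))
        for pwm in pwms:
            if len(rec) >= pwm.length:
                hits.extend(scan_pwm(pwm, rec, args.threshold))

    write_hits_bed(hits, out / "motif_hits.bed")
    blocks = group_by_family(hits, table)
    with open(out / "family_blocks.tsv", "w") as handle:
        handle.write("#seq\tstart\tend\tfamily\tn_hits\tmacrophage_expressed\n")
        for b in blocks:
            handle.write(f"{b.seq_id}\t{b.start}\t{b.end}\t{b.family}\t"
                         f"{len(b.hits)}\t{'yes' if b.macrophage_expressed else 'no'}\n")

    census = {}
    for b in blocks:
        census[b.family] = census.get(b.family, 0) + 1
    print("family blocks:", ", ".join(f"{k}={v}" for k, v in sorted(census.items())))

    report = find_core_element(consensi)
    with open(out / "core_element.json", "w") as handle:
        json.dump(report.to_dict(), handle, indent=2)
    print(f"core present in all clades: {report.core_present}")
    for c in report.clades:
        if c.present:
            print(f"  {c.clade}: {c.ap1.matched} ({c.ap1_pattern}) + {c.spacer} bp "
                  f"+ {c.pu1.matched} [{c.orientation} strand]")
        else:
            print(f"  {c.clade}: core not found")
    print(f"wrote annotation to {out}")


if __name__ == "__main__":
    main()
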