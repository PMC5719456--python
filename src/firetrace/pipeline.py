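"""Full-analysis orchestration: one config in, one output directory out.

Stage order mirrors the analysis the package reproduces: optional
element extraction from genomic context, per-clade progressive
alignment and common-length trimming, consensus calling, p-distance
neighbor-joining trees, cross-clade dot-matrix comparison of the
consensi, motif annotation and the cross-clade AP1/PU.1 core report.
Every stage consumes and produces plain standard formats (FASTA,
Newick, TSV, BED, JSON); a manifest records checksums so an unchanged
rerun is skipped and a changed one is reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from itertools import combinations

import yaml

from firetrace import __version__
from firetrace.align import (Alignment, consensus, progressive_msa,
                             trim_common, write_aligned_fasta)
from firetrace.dotmatrix import DotMatrixParams, dot_matrix, write_segments_tsv
from firetrace.extract import ScoringScheme, locate_element, trim_to_query
from firetrace.io import SequenceRecord, read_fasta, write_fasta
from firetrace.motifs import (find_core_element, group_by_family, pfm_to_pwm,
                              read_family_table, read_jaspar, scan_pwm,
                              write_hits_bed)
from firetrace.phylogeny import (neighbor_joining, p_distance_matrix,
                                 write_distance_tsv, write_newick)

log = logging.getLogger("firetrace")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class CladeInput:
    name: str
    fasta: str | None = None          # element sequences, ready to align
    context_fasta: str | None = None  # larger genomic context to extract from
    query_fasta: str | None = None    # query element for extraction

    def __post_init__(self) -> None:
        if self.fasta is None and (self.context_fasta is None or self.query_fasta is None):
            raise ValueError(
                f"clade {self.name!r}: give either 'fasta' or both "
                f"'context_fasta' and 'query_fasta'"
            )


@dataclass
class RunConfig:
    """Everything a run needs; defaults are the analysis' published values
    (dot-matrix window 15 at 70% identity, PWM threshold 0.85)."""

    clades: list[CladeInput]
    out_dir: str
    pfm_file: str | None = None
    family_table: str | None = None
    window: int = 15
    min_identity: float = 0.70
    pwm_threshold: float = 0.85
    plurality: float = 0.5
    ambiguity_floor: float = 0.25
    max_spacer: int = 20
    seed: int = 0
    scoring: ScoringScheme = field(default_factory=ScoringScheme)

    def __post_init__(self) -> None:
        if not self.clades:
            raise ValueError("config lists no clades")
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity out of range (0, 1]")
        if not (0 < self.pwm_threshold <= 1):
            raise ValueError("pwm_threshold out of range (0, 1]")
        for c in self.clades:
            for path in (c.fasta, c.context_fasta, c.query_fasta):
                if path is not None and not os.path.exists(path):
                    raise FileNotFoundError(f"clade {c.name!r}: missing {path}")
        for path in (self.pfm_file, self.family_table):
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(path)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        payload = {
            "version": __version__,
            "params": [self.window, self.min_identity, self.pwm_threshold,
                       self.plurality, self.ambiguity_floor, self.max_spacer,
                       self.seed, self.scoring.match, self.scoring.mismatch,
                       self.scoring.gap_open, self.scoring.gap_extend],
            "inputs": sorted(
                (c.name, _sha256_file(p))
                for c in self.clades
                for p in (c.fasta, c.context_fasta, c.query_fasta) if p
            ),
            "pfm": _sha256_file(self.pfm_file) if self.pfm_file else None,
            "families": _sha256_file(self.family_table) if self.family_table else None,
        }
        h.update(json.dumps(payload, sort_keys=True).encode())
        return h.hexdigest()


def load_config(path) -> RunConfig:
    with open(path) as handle:
        data = yaml.safe_load(handle)
    base = os.path.dirname(os.path.abspath(path))

    def resolve(p):
        return p if p is None or os.path.isabs(p) else os.path.join(base, p)

    clades = []
    for name, spec in data["clades"].items():
        if isinstance(spec, str):
            spec = {"fasta": spec}
        clades.append(CladeInput(name=name,
                                 fasta=resolve(spec.get("fasta")),
                                 context_fasta=resolve(spec.get("context_fasta")),
                                 query_fasta=resolve(spec.get("query_fasta"))))
    params = data.get("params", {})
    return RunConfig(clades=clades,
                     out_dir=resolve(data["out_dir"]),
                     pfm_file=resolve(data.get("pfm_file")),
                     family_table=resolve(data.get("family_table")),
                     **{k: params[k] for k in
                        ("window", "min_identity", "pwm_threshold", "plurality",
                         "ambiguity_floor", "max_spacer", "seed") if k in params})


def _sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> str:
    """Run every stage; returns the output directory.

    A rerun with unchanged inputs and parameters is detected through the
    manifest's config hash and skipped.  Any stage failure aborts with
    the stage name; partial outputs are kept next to a FAILED marker.
    """
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    manifest_path = os.path.join(out, "manifest.json")
    cfg_hash = config.content_hash()
    if os.path.exists(manifest_path):
        with open(manifest_path) as handle:
            previous = json.load(handle)
        if previous.get("config_hash") == cfg_hash and all(
            os.path.exists(os.path.join(out, f)) and _sha256_file(os.path.join(out, f)) == digest
            for f, digest in previous.get("outputs", {}).items()
        ):
            log.info("unchanged config and outputs; skipping recompute")
            return out

    failed_marker = os.path.join(out, "FAILED")
    if os.path.exists(failed_marker):
        os.remove(failed_marker)
    outputs: dict[str, str] = {}
    stages_done: list[str] = []
    consensi = []
    try:
        clade_records = _stage_collect(config, out, outputs)
        stages_done.append("collect")
        for clade, records in clade_records.items():
            aln, cons = _stage_clade(config, out, outputs, clade, records)
            consensi.append(cons)
            stages_done.append(f"align:{clade}")
        _stage_dotplots(config, out, outputs, consensi)
        stages_done.append("dotplots")
        _stage_motifs(config, out, outputs, consensi)
        stages_done.append("motifs")
    except PipelineError:
        with open(failed_marker, "w") as handle:
            handle.write("pipeline failed; see log\n")
        raise
    except Exception as exc:
        stage = "unknown"
        with open(failed_marker, "w") as handle:
            handle.write(f"pipeline failed: {exc}\n")
        raise PipelineError(stage, str(exc)) from exc

    manifest = {
        "tool": "firetrace",
        "version": __version__,
        "config_hash": cfg_hash,
        "stages": stages_done,
        "outputs": {f: _sha256_file(os.path.join(out, f)) for f in outputs},
        "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(manifest_path, "w") as handle:
        json.dump(manifest, handle, indent=2)
    return out


def _stage_collect(config: RunConfig, out, outputs) -> dict[str, list[SequenceRecord]]:
    """Read per-clade elements, extracting from context where requested."""
    clade_records = {}
    for clade in config.clades:
        try:
            if clade.fasta:
                records = read_fasta(clade.fasta, clade=clade.name)
            else:
                query = read_fasta(clade.query_fasta, clade=clade.name)[0]
                targets = read_fasta(clade.context_fasta, clade=clade.name)
                records, report_rows = [], []
                for target in targets:
                    hit = locate_element(query, target, config.scoring)
                    if hit is None:
                        log.warning("extract: no credible hit of %s in %s",
                                    query.id, target.id)
                        report_rows.append((query.id, target.id, "not_found"))
                        continue
                    element = trim_to_query(hit, target)
                    records.append(SequenceRecord(id=target.id, seq=element.seq,
                                                  clade=clade.name,
                                                  source_note=element.source_note))
                    report_rows.append(
                        (query.id, target.id,
                         f"{hit.target_span[0] + 1}-{hit.target_span[1]}",
                         hit.strand, f"{hit.score:g}",
                         f"{hit.aligned_identity:.4f}"))
                report = f"{clade.name}.extraction.tsv"
                with open(os.path.join(out, report), "w") as handle:
                    for row in report_rows:
                        handle.write("\t".join(map(str, row)) + "\n")
                outputs[report] = None
                fasta = f"{clade.name}.elements.fa"
                write_fasta(records, os.path.join(out, fasta))
                outputs[fasta] = None
            if not records:
                raise ValueError("no usable records")
            clade_records[clade.name] = records
        except Exception as exc:
            raise PipelineError(f"collect:{clade.name}", str(exc)) from exc
    return clade_records


def _stage_clade(config: RunConfig, out, outputs, clade: str,
                 records: list[SequenceRecord]):
    try:
        if len(records) == 1:
            log.warning("clade %s has a single sequence; alignment skipped "
                        "and the sequence is its own consensus", clade)
            aln = Alignment(records=[(records[0].id, records[0].seq)])
            from firetrace.align import ConsensusSequence
            cons = ConsensusSequence(clade=clade, seq=records[0].seq,
                                     support=[1.0] * len(records[0].seq))
        else:
            aln = trim_common(progressive_msa(records))
            cons = consensus(aln, plurality=config.plurality,
                             ambiguity_floor=config.ambiguity_floor, clade=clade)
        aln_file = f"{clade}.aln.fa"
        write_aligned_fasta(aln, os.path.join(out, aln_file))
        outputs[aln_file] = None
        cons_file = f"{clade}.consensus.fa"
        write_fasta(cons.as_record(), os.path.join(out, cons_file))
        outputs[cons_file] = None
        if len(records) >= 2:
            dm = p_distance_matrix(aln)
            dm_file = f"{clade}.pdist.tsv"
            write_distance_tsv(dm, os.path.join(out, dm_file))
            outputs[dm_file] = None
            if len(records) >= 3:
                tree = neighbor_joining(dm)
                nwk_file = f"{clade}.nwk"
                write_newick(tree, os.path.join(out, nwk_file))
                outputs[nwk_file] = None
        return aln, cons
    except Exception as exc:
        raise PipelineError(f"align:{clade}", str(exc)) from exc


def _stage_dotplots(config: RunConfig, out, outputs, consensi) -> None:
    params = DotMatrixParams(window=config.window,
                             min_identity=config.min_identity)
    for a, b in combinations(consensi, 2):
        try:
            segments = dot_matrix(a.as_record(), b.as_record(), params)
            name = f"dotplot.{a.clade}_vs_{b.clade}.tsv"
            write_segments_tsv(segments, a.clade, b.clade,
                               os.path.join(out, name))
            outputs[name] = None
        except Exception as exc:
            raise PipelineError(f"dotplot:{a.clade}_vs_{b.clade}", str(exc)) from exc


def _stage_motifs(config: RunConfig, out, outputs, consensi) -> None:
    try:
        family_table = (read_family_table(config.family_table)
                        if config.family_table else {})
        if config.pfm_file:
            pfms = read_jaspar(config.pfm_file, family_table)
            pwms = [pfm_to_pwm(p) for p in pfms]
            all_hits = []
            for cons in consensi:
                rec = cons.as_record()
                for pwm in pwms:
                    if len(rec) >= pwm.length:
                        all_hits.extend(scan_pwm(pwm, rec, config.pwm_threshold))
            bed = "motif_hits.bed"
            write_hits_bed(all_hits, os.path.join(out, bed))
            outputs[bed] = None
            blocks = group_by_family(all_hits, family_table)
            fam_file = "family_blocks.tsv"
            with open(os.path.join(out, fam_file), "w") as handle:
                handle.write("#seq\tstart\tend\tfamily\tn_hits\tmacrophage_expressed\n")
                for blk in blocks:
                    handle.write(f"{blk.seq_id}\t{blk.start}\t{blk.end}\t"
                                 f"{blk.family}\t{len(blk.hits)}\t"
                                 f"{'yes' if blk.macrophage_expressed else 'no'}\n")
            outputs[fam_file] = None
        report = find_core_element(consensi, max_spacer=config.max_spacer)
        with open(os.path.join(out, "core_element.json"), "w") as handle:
            json.dump(report.to_dict(), handle, indent=2)
        outputs["core_element.json"] = None
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("motifs", str(exc)) from exc


def report_summary(output_dir: str) -> str:
    """Human-readable synopsis of a completed run."""
    manifest_path = os.path.join(output_dir, "manifest.json")
    missing = []
    if not os.path.exists(manifest_path):
        missing.append("manifest.json")
    core_path = os.path.join(output_dir, "core_element.json")
    if not os.path.exists(core_path):
        missing.append("core_element.json")
    if missing:
        raise ValueError(f"incomplete run; missing: {', '.join(missing)}")
    with open(manifest_path) as handle:
        manifest = json.load(handle)
    lines = [f"firetrace {manifest['version']} run summary",
             f"config hash {manifest['config_hash'][:12]}"]
    clades = sorted({f.split(".")[0] for f in manifest["outputs"]
                     if f.endswith(".aln.fa")})
    from firetrace.align import read_aligned_fasta
    for clade in clades:
        aln = read_aligned_fasta(os.path.join(output_dir, f"{clade}.aln.fa"))
        lines.append(f"clade {clade}: {len(aln.records)} sequences, "
                     f"alignment length {aln.length}")
        if len(aln.records) >= 2:
            dm = p_distance_matrix(aln)
            import numpy as np
            tri = dm.data[np.triu_indices(len(dm.ids), 1)]
            lines.append(f"  mean within-clade p-distance {tri.mean():.4f}")
        nwk = os.path.join(output_dir, f"{clade}.nwk")
        if os.path.exists(nwk):
            with open(nwk) as handle:
                lines.append("  tree " + handle.read().strip())
    bed = os.path.join(output_dir, "motif_hits.bed")
    if os.path.exists(bed):
        census: dict[str, int] = {}
        with open(bed) as handle:
            for line in handle:
                fam = line.rstrip("\n").split("\t")[7]
                census[fam] = census.get(fam, 0) + 1
        lines.append("motif family census: " +
                     ", ".join(f"{k}={v}" for k, v in sorted(census.items())))
    else:
        lines.append("motif scan: not run (no PFM file)")
    with open(core_path) as handle:
        core = json.load(handle)
    lines.append(f"core AP1/PU.1 element present in all clades: {core['core_present']}")
    for c in core["clades"]:
        if c["present"]:
            lines.append(f"  {c['clade']}: {c['ap1_matched']} + "
                         f"{c['spacer']} bp + {c['pu1_matched']} "
                         f"({c['orientation']} strand)")
        else:
            lines.append(f"  {c['clade']}: core not found")
    return "\n".join(lines)
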