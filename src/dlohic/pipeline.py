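"""End-to-end orchestration of the pipeline stages.

Each stage writes its outputs and a summary JSON under a numbered
subdirectory of the configured output path, so a later stage (or a
re-run) can pick up from the previous stage's files:

    01_preprocess/   tag FASTQ pairs per linker type, linker hit table
    02_mapping/      per-side alignment tables
    03_pairs/        classified, deduplicated pairs table
    04_matrix/       sparse triplet matrices per resolution + bins BED
    report.html / report.json
"""

from __future__ import annotations

import json
import shutil
import time
from pathlib import Path

from ._seq import read_fasta, read_fastq
from .config import Config
from .fragments import (FragmentIndex, RestrictionSite, digest_genome,
                        strand_end_table)
from .mapping import (BwaAligner, MismatchScanAligner, iterative_map,
                      read_alignment_table, write_alignment_table)
from .matrix import MatrixSpec, bin_pairs, oe_normalize
from .pairs import (PairClassParams, _sort_key, classify_pair, deduplicate,
                    join_pairs, summarize_pairs, write_pairs)
from .preprocess import (DetectionError, align_linker_batch,
                         detect_adapter_consensus, discover_linker_and_site,
                         enumerate_full_linkers, split_by_linker,
                         trim_adapter_batch)
from .report import build_report
from .simulate import SimParams, simulate_library

__all__ = ["run_pipeline", "stage_preprocess", "stage_mapping", "stage_pairs",
           "stage_matrix"]


def _write_summary(out_dir: Path, name: str, summary: dict) -> None:
    (out_dir / f"{name}.summary.json").write_text(json.dumps(summary, indent=2))


def stage_preprocess(cfg: Config, out_root: Path) -> dict:
    """Adapter detection/trimming, linker location, tag splitting."""
    out = out_root / "01_preprocess"
    out.mkdir(parents=True, exist_ok=True)
    reads = list(read_fastq(cfg.data_file))
    half_linkers = list(cfg.half_linkers)
    restriction = cfg.restriction
    detected = False
    if not half_linkers or not restriction:
        found_halves, found_site = discover_linker_and_site(
            reads, sample_size=cfg.detect_sample_size
        )
        if not half_linkers:
            half_linkers = found_halves
        if not restriction:
            restriction = found_site
        detected = True
    linkers = enumerate_full_linkers(half_linkers)
    aparams = cfg.adapter_params()
    lparams = cfg.linker_align_params()
    adapter = cfg.adapter_seq
    if not adapter:
        adapter = detect_adapter_consensus(reads, linkers, aparams, lparams) or ""
    if adapter:
        reads, adapter_starts = trim_adapter_batch(reads, adapter, aparams)
    else:
        adapter_starts = [None] * len(reads)
    hits = align_linker_batch(reads, linkers, lparams, adapter_starts)
    split = split_by_linker(zip(reads, hits), out, cfg.min_tag_length)
    scores = sorted(h.align_score for h in hits if h is not None)
    summary = {
        "adapter": adapter,
        "adapter_detected": not cfg.adapter_seq and bool(adapter),
        "half_linkers": half_linkers,
        "restriction": restriction,
        "linker_detected": detected,
        "full_linker_types": linkers.type_labels,
        "counts": split["counts"],
        "files": split["files"],
        "align_score_quartiles": (
            [scores[0], scores[len(scores) // 2], scores[-1]] if scores else []
        ),
    }
    _write_summary(out, "preprocess", summary)
    return summary


def _make_aligner(cfg: Config, backend: str):
    if backend == "builtin":
        return MismatchScanAligner(read_fasta(cfg.genome_file))
    if backend == "bwa" or (backend == "auto" and shutil.which("bwa")):
        return BwaAligner(cfg.genome_file,
                          algorithm="mem" if cfg.reads_type == "long" else "aln",
                          threads=cfg.threads)
    return MismatchScanAligner(read_fasta(cfg.genome_file))


def stage_mapping(cfg: Config, out_root: Path, aligner=None,
                  backend: str = "auto") -> dict:
    """Map every linker type's left/right tags; write per-side tables."""
    pre = out_root / "01_preprocess"
    out = out_root / "02_mapping"
    out.mkdir(parents=True, exist_ok=True)
    summary_pre = json.loads((pre / "preprocess.summary.json").read_text())
    if aligner is None:
        aligner = _make_aligner(cfg, backend)
    params = cfg.mapping_params()
    categories = {"unique": 0, "multi": 0, "unmapped": 0}
    for side in ("r1", "r2"):
        side_name = "left" if side == "r1" else "right"
        alns = []
        for t, files in summary_pre["files"].items():
            fq = pre / [f for f in files if f".{side}." in f][0]
            tags = list(read_fastq(fq))
            # prefix ids with linker type so sides join within type
            tags = [type(t2)(f"{t}:{t2.read_id}", t2.seq, t2.qual) for t2 in tags]
            alns.extend(iterative_map(tags, params, aligner, side=side_name))
        alns.sort(key=lambda a: a.read_id)
        for a in alns:
            categories[a.category] += 1
        write_alignment_table(out / f"{side_name}.tsv", alns)
    summary = {
        "algorithm": params.algorithm,
        "iterative": params.iterative,
        "unique_score_cutoff": params.unique_score_cutoff,
        "categories": categories,
    }
    _write_summary(out, "mapping", summary)
    return summary


def stage_pairs(cfg: Config, out_root: Path) -> dict:
    """Join, classify, deduplicate; write the pairs table."""
    mp = out_root / "02_mapping"
    out = out_root / "03_pairs"
    out.mkdir(parents=True, exist_ok=True)
    genome = read_fasta(cfg.genome_file)
    restriction = cfg.restriction
    if not restriction:
        summary_pre = json.loads(
            (out_root / "01_preprocess" / "preprocess.summary.json").read_text()
        )
        restriction = summary_pre["restriction"]
    site = RestrictionSite.from_string(restriction)
    index = digest_genome(genome, site)
    index.to_bed(out / "fragments.bed")
    left = [a for a in read_alignment_table(mp / "left.tsv") if a.category == "unique"]
    right = [a for a in read_alignment_table(mp / "right.tsv") if a.category == "unique"]
    linker_types = {a.read_id: a.read_id.split(":", 1)[0] for a in left}
    pairs, singletons = join_pairs(left, right, linker_types)
    params = PairClassParams(cfg.short_range_max, cfg.dup_window)
    pairs = [classify_pair(p, index, params) for p in pairs]
    pairs.sort(key=_sort_key)
    pairs = deduplicate(pairs, params)
    write_pairs(out / "pairs.tsv", pairs)
    summary = summarize_pairs(pairs, singletons)
    summary["strand_end_table"] = {
        row: {c: int(v) for c, v in cols.items()}
        for row, cols in strand_end_table(
            [p for p in pairs if p.cls == "valid" and not p.duplicate], index
        ).iterrows()
    }
    _write_summary(out, "pairs", summary)
    return summary


def stage_matrix(cfg: Config, out_root: Path) -> dict:
    """Bin valid pairs at every configured resolution; O/E for intra."""
    from .mapping import TagAlignment

    out = out_root / "04_matrix"
    out.mkdir(parents=True, exist_ok=True)
    genome = read_fasta(cfg.genome_file)
    sizes = {c: len(s) for c, s in genome.items()}
    pairs = []
    with open(out_root / "03_pairs" / "pairs.tsv") as fh:
        header = fh.readline()
        assert header.startswith("#")
        from .pairs import PairRecord

        for line in fh:
            f = line.rstrip("\n").split("\t")
            tl = TagAlignment(f[0], "left", f[1], int(f[2]), int(f[2]) + 1, f[3], 37, "unique")
            tr = TagAlignment(f[0], "right", f[4], int(f[5]), int(f[5]) + 1, f[6], 37, "unique")
            pairs.append(PairRecord(f[0], tl, tr, int(f[7]), int(f[8]), f[9],
                                    f[10], bool(int(f[11]))))
    summary: dict = {"resolutions": {}}
    for res in cfg.resolutions:
        spec = MatrixSpec(res, sizes)
        mats = bin_pairs(pairs, spec)
        total = 0
        for (c1, c2), m in mats.items():
            m.write_triplets(out / f"{c1}_{c2}_{res}.raw.txt")
            total += m.total
            if m.intra:
                oe_normalize(m).write_triplets(out / f"{c1}_{c2}_{res}.oe.txt")
        with open(out / f"bins_{res}.bed", "w") as fh:
            for chrom, size in sizes.items():
                for b in range(0, size, res):
                    fh.write(f"{chrom}\t{b}\t{min(b + res, size)}\t{b // res}\n")
        summary["resolutions"][str(res)] = {
            "matrices": len(mats),
            "binned_pairs": int(total),
        }
    _write_summary(out, "matrix", summary)
    return summary


def run_pipeline(cfg: Config, aligner=None, backend: str = "auto") -> dict:
    """Run every stage and build the report; returns the stage summaries."""
    out_root = Path(cfg.out_path)
    out_root.mkdir(parents=True, exist_ok=True)
    timings = {}
    summaries: dict[str, dict] = {}
    summaries["config"] = {
        "parameters": {
            "DataFile": cfg.data_file, "GenomeFile": cfg.genome_file,
            "AdapterSeq": cfg.adapter_seq or "(auto)",
            "HalfLinker": cfg.half_linker or "(auto)",
            "Restriction": cfg.restriction or "(auto)",
            "ReadsType": cfg.reads_type,
            "Resolutions": cfg.resolutions, "Threads": cfg.threads,
            "Iterative": cfg.iterative,
        }
    }
    for name, fn in (
        ("preprocess", lambda: stage_preprocess(cfg, out_root)),
        ("mapping", lambda: stage_mapping(cfg, out_root, aligner, backend)),
        ("pairs", lambda: stage_pairs(cfg, out_root)),
        ("matrix", lambda: stage_matrix(cfg, out_root)),
    ):
        t0 = time.perf_counter()
        summaries[name] = fn()
        timings[name] = round(time.perf_counter() - t0, 2)
    summaries["config"]["stage_seconds"] = timings
    build_report(summaries, out_root,
                 generated_at=time.strftime("%Y-%m-%d %H:%M:%S"))
    return summaries
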