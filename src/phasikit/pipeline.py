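"""End-to-end orchestration: filter -> map -> scan -> call -> extract ->
triggers -> targets -> TAS3 -> network, with a run manifest.

All randomness (FPR permutations) flows from the single config seed;
identical config + inputs give identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .annotate import (
    TasiArfMatch,
    classify_cis_trans,
    classify_tas3,
    export_network,
    find_tasiarf_matches,
    link_matches_to_loci,
    shared_phasirna_report,
    tas3_report,
)
from .degradome import DegradomeProfile, select_phasirna_targets, select_trigger_candidates
from .io_formats import (
    ReadPlacement,
    UniqueRead,
    filter_repeat_reads,
    map_reads,
    select_lengths,
    write_bed6,
    write_fasta,
    write_gff3,
)
from .loci import (
    Interval,
    PhasLocus,
    adjust_intervals,
    call_loci,
    estimate_fpr,
    extend_windows,
    extract_phasirnas,
    loci_gff3_rows,
    loci_to_frame,
    merge_windows,
    phasirna_count_matrix,
)
from .phasing import PhaseParams, PhaseWindow, scan_genome, windows_to_rows
from .sim import SimBundle

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    cycles: tuple[int, ...] = (21, 24)
    window_cycles: int = 10
    p_window: float = 0.05
    extend_bp: int = 100
    score_min: float = 5.0
    fdr: float = 0.05
    tasiarf_max_mm: int = 2
    trigger_max_mm: float = 5
    target_max_mm: float = 4
    gu_half_weight: bool = False
    unique_reads_only: bool = False
    seed: int = 0
    n_permutations: int = 200  # 0 skips the FPR report column

    def __post_init__(self) -> None:
        if self.score_min <= 0 or self.fdr <= 0 or self.extend_bp <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class PipelineInputs:
    genome: dict[str, str]
    libraries: dict[str, dict[str, int]]
    repeats: dict[str, str] = field(default_factory=dict)
    transcripts: dict[str, str] = field(default_factory=dict)
    transcript_coords: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)
    mirnas: dict[str, str] = field(default_factory=dict)
    tasiarfs: dict[str, str] = field(default_factory=dict)
    degradome: dict[str, dict[str, dict[int, int]]] = field(default_factory=dict)
    annotation: pd.DataFrame | None = None

    @classmethod
    def from_bundle(cls, bundle: SimBundle) -> "PipelineInputs":
        return cls(
            genome=dict(bundle.genome),
            libraries={lib: dict(c) for lib, c in bundle.libraries.items()},
            repeats=dict(bundle.repeats),
            transcripts=dict(bundle.transcripts),
            transcript_coords=dict(bundle.transcript_coords),
            mirnas=dict(bundle.mirnas),
            tasiarfs=dict(bundle.tasiarfs),
            degradome={lib: {t: dict(p) for t, p in d.items()} for lib, d in bundle.degradome.items()},
        )


@dataclass
class PipelineResult:
    windows: dict[int, list[PhaseWindow]]
    merged: list[Interval]
    loci: list[PhasLocus]
    placements: list[ReadPlacement]
    count_matrix: pd.DataFrame
    triggers: pd.DataFrame
    targets: pd.DataFrame
    tas3: list[TasiArfMatch]
    network: pd.DataFrame
    shared: pd.DataFrame
    annotation: pd.DataFrame | None
    manifest: dict


def _collapse_libraries(libraries: Mapping[str, Mapping[str, int]]) -> list[UniqueRead]:
    table: dict[str, dict[str, int]] = {}
    for lib in sorted(libraries):
        for seq, count in libraries[lib].items():
            entry = table.setdefault(seq, {})
            entry[lib] = entry.get(lib, 0) + int(count)
    return [UniqueRead(seq, counts) for seq, counts in sorted(table.items())]


def _degradome_profiles(inputs: PipelineInputs) -> list[DegradomeProfile]:
    return [
        DegradomeProfile(lib, {t: dict(p) for t, p in inputs.degradome[lib].items()})
        for lib in sorted(inputs.degradome)
    ]


def _lift_degradome_to_genome(inputs: PipelineInputs) -> dict[str, dict[str, dict[int, int]]]:
    """Degradome counts in genomic coordinates (plus-strand transcripts)."""
    lifted: dict[str, dict[str, dict[int, int]]] = {}
    for lib in sorted(inputs.degradome):
        per_contig: dict[str, dict[int, int]] = {}
        for tid, posmap in inputs.degradome[lib].items():
            coords = inputs.transcript_coords.get(tid)
            if coords is None:
                continue
            contig, gstart, gend, strand = coords
            if strand != "+":
                continue
            cmap = per_contig.setdefault(contig, {})
            for pos, count in posmap.items():
                gpos = gstart + pos - 1
                if gpos <= gend:
                    cmap[gpos] = cmap.get(gpos, 0) + count
        lifted[lib] = per_contig
    return lifted


def run_all(inputs: PipelineInputs, cfg: PipelineConfig) -> PipelineResult:
    """Run every stage in order on an input bundle.

    Stages lacking their inputs (no degradome, no transcripts, no tasiARFs)
    are skipped with a warning; locus calling always runs.
    """
    t0 = time.time()
    counts: dict[str, int] = {}
    contig_lengths = {c: len(s) for c, s in inputs.genome.items()}

    reads = _collapse_libraries(inputs.libraries)
    counts["unique_reads"] = len(reads)
    reads = filter_repeat_reads(reads, list(inputs.repeats.values())) if inputs.repeats else reads
    counts["after_repeat_filter"] = len(reads)
    reads = select_lengths(reads, cfg.cycles)
    counts["after_length_selection"] = len(reads)
    logger.info("reads: %s", counts)

    placements = map_reads(reads, inputs.genome) if reads else []
    counts["placements"] = len(placements)

    windows: dict[int, list[PhaseWindow]] = {}
    all_merged: list[Interval] = []
    for cycle in cfg.cycles:
        params = PhaseParams(cycle=cycle, window_cycles=cfg.window_cycles)
        wins = scan_genome(placements, params, contig_lengths, cfg.unique_reads_only)
        windows[cycle] = wins
        extended = extend_windows(wins, contig_lengths, cfg.p_window, cfg.extend_bp)
        merged = merge_windows(extended)
        logger.info(
            "cycle %d: %d windows, %d significant, %d merged", cycle, len(wins),
            len(extended), len(merged),
        )
        if merged:
            # The occupied-anchor scan is a lazy version of anchoring a
            # window at every genomic position (unoccupied anchors have
            # k = 0, p = 1); the BH universe must be that full test family.
            n_anchor_positions = sum(
                max(0, clen - params.window + 1) for clen in contig_lengths.values()
            )
            reference = [w.p_value for w in wins]
            reference += [1.0] * max(0, n_anchor_positions - len(reference))
            adjust_intervals(merged, {cycle: reference})
            if cfg.n_permutations >= 100:
                for i, iv in enumerate(merged):
                    iv.fpr = estimate_fpr(
                        iv, placements, params, cfg.n_permutations,
                        seed=cfg.seed + 1000 * cycle + i,
                    )
        all_merged.extend(merged)
    counts["merged_intervals"] = len(all_merged)

    loci = call_loci(all_merged, cfg.score_min, cfg.fdr)
    for locus in loci:
        locus.phasirnas = extract_phasirnas(locus, placements)
    counts["loci"] = len(loci)
    counts["phasirnas"] = sum(len(l.phasirnas) for l in loci)
    count_matrix = phasirna_count_matrix(loci)

    profiles = _degradome_profiles(inputs)
    lifted = _lift_degradome_to_genome(inputs) if inputs.degradome else {}

    # --- miRNA triggers of the called loci ---------------------------------
    triggers = pd.DataFrame()
    if inputs.mirnas and inputs.degradome and loci:
        locus_records = []
        for locus in loci:
            seq = inputs.genome[locus.contig][locus.start - 1 : locus.end]
            profile = {
                lib: {
                    gpos - locus.start + 1: c
                    for gpos, c in lifted.get(lib, {}).get(locus.contig, {}).items()
                    if locus.start <= gpos <= locus.end
                }
                for lib in sorted(lifted)
            }
            locus_records.append(
                {
                    "name": locus.name, "sequence": seq, "start": locus.start,
                    "anchor": locus.anchor, "cycle": locus.cycle,
                    "phased_positions": [p.position for p in locus.phasirnas],
                    "profile": profile,
                }
            )
        triggers = select_trigger_candidates(
            inputs.mirnas, locus_records, profiles, cfg.trigger_max_mm, cfg.gu_half_weight
        )
    elif loci:
        logger.warning("no miRNAs or degradome provided: trigger stage skipped")
    counts["trigger_candidates"] = len(triggers)

    # --- phasiRNA targets ---------------------------------------------------
    targets = pd.DataFrame()
    phasirna_seqs = {p.name: p.sequence for l in loci for p in l.phasirnas}
    if phasirna_seqs and inputs.transcripts and inputs.degradome:
        targets = select_phasirna_targets(
            phasirna_seqs, inputs.transcripts, profiles, cfg.target_max_mm,
            cfg.gu_half_weight,
        )
    elif phasirna_seqs:
        logger.warning("no transcripts or degradome provided: target stage skipped")
    counts["targets"] = len(targets)

    annotation_df = inputs.annotation
    locus_families: dict[str, str] | None = None
    transcript_families: dict[str, str] | None = None
    if annotation_df is not None and {"name", "family"} <= set(annotation_df.columns):
        locus_families = dict(zip(annotation_df["name"], annotation_df["family"]))
    if not targets.empty:
        targets = classify_cis_trans(
            targets, loci, inputs.transcript_coords, locus_families, transcript_families
        )
        counts["cis_targets"] = int((targets["target_class"] == "cis").sum())

    # --- TAS3 ---------------------------------------------------------------
    tas3: list[TasiArfMatch] = []
    if inputs.tasiarfs:
        mir390s = {n: s for n, s in inputs.mirnas.items() if "390" in n} or dict(inputs.mirnas)
        tas3 = find_tasiarf_matches(inputs.tasiarfs, inputs.genome, cfg.tasiarf_max_mm)
        for match in tas3:
            classify_tas3(match, inputs.genome, mir390s, profiles=())
        link_matches_to_loci(tas3, loci)
    counts["tasiarf_matches"] = len(tas3)
    counts["tas3_like"] = sum(1 for m in tas3 if m.classification == "TAS3-like")

    shared = shared_phasirna_report(loci)
    network = export_network(loci, targets)

    cfg_json = json.dumps(dataclasses.asdict(cfg), sort_keys=True)
    digest_src = "\n".join(
        [
            loci_to_frame(loci).to_csv(index=False),
            triggers.to_csv(index=False),
            targets.to_csv(index=False),
            network.to_csv(index=False),
        ]
    )
    manifest = {
        "phasikit_version": __version__,
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "results_sha256": hashlib.sha256(digest_src.encode()).hexdigest(),
        "seed": cfg.seed,
        "counts": counts,
        "elapsed_s": round(time.time() - t0, 3),
    }
    logger.info("pipeline finished: %s", counts)
    return PipelineResult(
        windows=windows,
        merged=all_merged,
        loci=loci,
        placements=placements,
        count_matrix=count_matrix,
        triggers=triggers,
        targets=targets,
        tas3=tas3,
        network=network,
        shared=shared,
        annotation=annotation_df,
        manifest=manifest,
    )


def write_results(result: PipelineResult, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    loci_df = loci_to_frame(result.loci)
    paths["loci_tsv"] = outdir / "loci.tsv"
    loci_df.to_csv(paths["loci_tsv"], sep="\t", index=False)
    paths["loci_gff3"] = outdir / "loci.gff3"
    write_gff3(paths["loci_gff3"], loci_gff3_rows(result.loci))
    paths["loci_bed"] = outdir / "loci.bed"
    write_bed6(
        paths["loci_bed"],
        [
            {"contig": l.contig, "start": l.start, "end": l.end, "name": l.name,
             "score": int(min(1000, l.max_phase_score * 10))}
            for l in result.loci
        ],
    )
    paths["phasirnas_fa"] = outdir / "phasirnas.fa"
    write_fasta(
        paths["phasirnas_fa"],
        {p.name: p.sequence for l in result.loci for p in l.phasirnas},
    )
    paths["count_matrix"] = outdir / "phasirna_counts.tsv"
    result.count_matrix.to_csv(paths["count_matrix"], sep="\t")
    for cycle, wins in result.windows.items():
        p = outdir / f"windows_{cycle}.tsv"
        pd.DataFrame(windows_to_rows(wins)).to_csv(p, sep="\t", index=False)
        paths[f"windows_{cycle}"] = p
    for name, df in (
        ("triggers", result.triggers),
        ("targets", result.targets),
        ("network", result.network),
        ("shared_phasirnas", result.shared),
    ):
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    paths["tas3"] = outdir / "tas3.tsv"
    tas3_report(result.tas3).to_csv(paths["tas3"], sep="\t", index=False)
    paths["manifest"] = outdir / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(result.manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
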