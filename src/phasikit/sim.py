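"""Synthetic small-RNA study generator.

Emulates the statistical structure the PHAS analysis assumes, so every
downstream stage is testable without external downloads: a random genome
with implanted phased 21/24-nt read clusters showing duplex 2-nt 3'-overhang
geometry on both strands, unphased background reads (a fraction copied from
a repeat set), a trigger miRNA per locus whose complementary site's inferred
cleavage coincides with the first phased position, degradome profiles with
signal at the true cleavage positions, and TAS3-like loci carrying two
miR390-style sites flanking a conserved tasiARF copy.

What is emulated: multi-library phased clusters, heavy-tailed (log-normal)
phased abundances, Poisson background, cleavage-anchored degradome signal.
What is not: sequencing errors, adapters, quality scores, genome repeats
beyond the explicit repeat FASTA, or any resemblance to a real genome's
composition beyond GC content.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np

from .io_formats import read_fasta, revcomp, write_collapsed_fasta, write_degradome_tsv, write_fasta, write_gff3

TISSUES = ("root", "leaf", "flower")
DEGRADOME_LIBRARIES = ("leaf", "root")

_BASES = np.array(list("ACGT"))


class PlacementError(RuntimeError):
    """Genome too short to place the requested loci without overlap."""


@dataclass(frozen=True)
class SimConfig:
    seed: int = 1
    genome_length: int = 100_000
    n_contigs: int = 2
    gc_content: float = 0.4
    n_phas_21: int = 5
    n_phas_24: int = 2
    cycles_per_locus: int = 10
    phased_read_abundance: float = 20.0
    n_libraries: int = 9
    background_read_density: float = 50.0  # unphased reads per kb of genome
    background_abundance: float = 3.0
    repeat_fraction: float = 0.1
    trigger_mirna_length: int = 22
    degradome_signal: int = 50
    degradome_noise_density: float = 5.0  # reads per kb of transcript
    n_tas3_like: int = 1

    def __post_init__(self) -> None:
        for name in (
            "genome_length", "n_contigs", "n_phas_21", "n_phas_24",
            "cycles_per_locus", "n_libraries", "degradome_signal", "n_tas3_like",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if self.cycles_per_locus < 4:
            raise ValueError("cycles_per_locus must be >= 4 so k >= 3 is reachable")
        if self.n_libraries < 1 or self.n_contigs < 1:
            raise ValueError("need at least one library and one contig")

    @property
    def library_names(self) -> list[str]:
        """Nine libraries are grouped as triplicates per tissue; any other
        count falls back to generic names."""
        if self.n_libraries % len(TISSUES) == 0:
            per = self.n_libraries // len(TISSUES)
            return [f"{t}{i + 1}" for t in TISSUES for i in range(per)]
        return [f"lib{i + 1}" for i in range(self.n_libraries)]


@dataclass
class TruthRecord:
    locus_id: str
    contig: str
    start: int
    end: int
    cycle: int
    strand_of_trigger_site: str
    trigger_name: str | None
    phased_positions: list[int]
    locus_class: str  # PHAS | TAS3-like | background-only
    transcript_id: str | None = None
    transcript_start: int | None = None
    transcript_end: int | None = None
    tasiarf: str | None = None


@dataclass
class SimBundle:
    config: SimConfig
    genome: dict[str, str]
    libraries: dict[str, dict[str, int]]  # lib -> sequence -> count
    degradome: dict[str, dict[str, dict[int, int]]]  # lib -> tid -> pos -> count
    transcripts: dict[str, str]
    transcript_coords: dict[str, tuple[str, int, int, str]]
    mirnas: dict[str, str]
    repeats: dict[str, str]
    tasiarfs: dict[str, str]
    truth: list[TruthRecord] = field(default_factory=list)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every output file; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["genome"] = outdir / "genome.fa"
        write_fasta(paths["genome"], self.genome)
        for lib in self.libraries:
            p = outdir / f"reads_{lib}.fa"
            write_collapsed_fasta(p, self.libraries[lib], prefix=f"{lib}_read")
            paths[f"reads_{lib}"] = p
        for lib in self.degradome:
            p = outdir / f"degradome_{lib}.tsv"
            write_degradome_tsv(p, self.degradome[lib])
            paths[f"degradome_{lib}"] = p
        paths["transcripts"] = outdir / "transcripts.fa"
        write_fasta(paths["transcripts"], self.transcripts)
        paths["transcript_coords"] = outdir / "transcripts.tsv"
        with open(paths["transcript_coords"], "w") as fh:
            fh.write("transcript_id\tcontig\tstart\tend\tstrand\n")
            for tid in sorted(self.transcript_coords):
                contig, start, end, strand = self.transcript_coords[tid]
                fh.write(f"{tid}\t{contig}\t{start}\t{end}\t{strand}\n")
        paths["mirnas"] = outdir / "mirnas.fa"
        write_fasta(paths["mirnas"], self.mirnas)
        paths["repeats"] = outdir / "repeats.fa"
        write_fasta(paths["repeats"], self.repeats)
        paths["tasiarfs"] = outdir / "tasiarfs.fa"
        write_fasta(paths["tasiarfs"], self.tasiarfs)
        paths["truth_json"] = outdir / "truth.json"
        with open(paths["truth_json"], "w") as fh:
            json.dump([dataclasses.asdict(t) for t in self.truth], fh, indent=1, sort_keys=True)
            fh.write("\n")
        paths["truth_gff3"] = outdir / "truth.gff3"
        write_gff3(
            paths["truth_gff3"],
            [
                {
                    "contig": t.contig, "type": "siRNA_locus", "start": t.start,
                    "end": t.end, "strand": ".",
                    "attributes": f"ID={t.locus_id};class={t.locus_class};cycle={t.cycle}",
                }
                for t in self.truth
            ],
        )
        return paths

    def file_digests(self, outdir: str | Path) -> dict[str, str]:
        """SHA-256 of every written output (determinism contract)."""
        paths = self.write(outdir)
        return {
            name: hashlib.sha256(path.read_bytes()).hexdigest()
            for name, path in sorted(paths.items())
        }


def default_tasiarf_fasta() -> dict[str, str]:
    """The shipped conserved tasiARF payload set (user-overridable)."""
    with resources.as_file(resources.files("phasikit.data") / "tasiarfs.fa") as p:
        return read_fasta(p)


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _lognormal_count(rng: np.random.Generator, mean: float) -> int:
    return max(1, int(round(rng.lognormal(np.log(mean), 0.5))))


def simulate_dataset(
    config: SimConfig, tasiarfs: Mapping[str, str] | None = None
) -> SimBundle:
    """Generate the full synthetic bundle for ``config``.

    Identical configs (including seed) reproduce byte-identical outputs.
    Raises :class:`PlacementError` when the genome cannot host the requested
    implants without overlap.
    """
    rng = np.random.default_rng(config.seed)
    tasiarfs = dict(tasiarfs) if tasiarfs is not None else default_tasiarf_fasta()

    repeats = {f"repeat{i + 1}": _random_seq(rng, 500, config.gc_content) for i in range(3)}

    contig_len = config.genome_length // config.n_contigs
    contig_names = [f"contig{i + 1}" for i in range(config.n_contigs)]
    genome_arrays = {
        name: np.array(list(_random_seq(rng, contig_len, config.gc_content)))
        for name in contig_names
    }

    # --- plan implants -----------------------------------------------------
    m = config.cycles_per_locus
    plan: list[tuple[str, int]] = (
        [("PHAS", 21)] * config.n_phas_21
        + [("PHAS", 24)] * config.n_phas_24
        + [("TAS3-like", 21)] * config.n_tas3_like
    )
    margin_up = 50
    # distinct implants must stay distinct after the 100-bp extension and
    # overlap-merge of the caller, including merges bridged by chance
    # significant background windows chaining through the gap
    min_gap = 2000
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in contig_names}

    def place(slot_len: int) -> tuple[str, int]:
        for _ in range(400):
            contig = contig_names[int(rng.integers(0, config.n_contigs))]
            if contig_len < slot_len + 2:
                continue
            start = int(rng.integers(1, contig_len - slot_len))
            end = start + slot_len - 1
            if all(end + min_gap < s or start - min_gap > e for s, e in occupied[contig]):
                occupied[contig].append((start, end))
                return contig, start
        raise PlacementError(
            f"could not place a {slot_len}-nt implant in a "
            f"{config.n_contigs}x{contig_len}-nt genome without overlap"
        )

    mirnas: dict[str, str] = {}
    mir390_name = None
    if config.n_tas3_like:
        mir390_name = "miR390-sim"
        mirnas[mir390_name] = _random_seq(rng, 21)
    implants: list[dict] = []
    arf_names = sorted(tasiarfs)
    for idx, (locus_class, cycle) in enumerate(plan):
        margin_down = 80 if locus_class == "TAS3-like" else 40
        slot_len = margin_up + m * cycle + margin_down
        contig, slot_start = place(slot_len)
        p1 = slot_start + margin_up
        region_end = p1 + m * cycle - 1
        record: dict = {
            "class": locus_class, "cycle": cycle, "contig": contig,
            "p1": p1, "region_end": region_end,
        }
        if locus_class == "PHAS":
            trig_name = f"miR-sim{idx + 1}"
            trig = _random_seq(rng, config.trigger_mirna_length)
            mirnas[trig_name] = trig
            record["trigger"] = trig_name
            # site [p1+10-L, p1+9]: expected cleavage (t_end - 9) is exactly p1
            L = len(trig)
            site = revcomp(trig)
            genome_arrays[contig][p1 + 9 - L : p1 + 9] = list(site)
            record["cleavages"] = [p1]
        else:  # TAS3-like: two miR390 sites flanking a tasiARF copy
            assert mir390_name is not None
            trig = mirnas[mir390_name]
            record["trigger"] = mir390_name
            site = revcomp(trig)
            L = len(trig)
            genome_arrays[contig][p1 + 9 - L : p1 + 9] = list(site)  # 5' site
            arf = arf_names[idx % len(arf_names)]
            arf_seq = tasiarfs[arf]
            pos_arf = p1 + (m // 2) * cycle  # in-register phased position
            genome_arrays[contig][pos_arf - 1 : pos_arf - 1 + len(arf_seq)] = list(arf_seq)
            record["tasiarf"] = arf
            t3_start = region_end + 10
            genome_arrays[contig][t3_start - 1 : t3_start - 1 + L] = list(site)  # 3' site
            record["site3_end"] = t3_start + L - 1
            record["cleavages"] = [p1, t3_start + L - 1 - 9]
        implants.append(record)

    genome = {name: "".join(arr) for name, arr in genome_arrays.items()}
    lib_names = config.library_names
    libraries: dict[str, dict[str, int]] = {lib: {} for lib in lib_names}

    def add_read(lib: str, seq: str, count: int) -> None:
        libraries[lib][seq] = libraries[lib].get(seq, 0) + count

    # --- phased reads: plus strand plus exact duplex partners --------------
    truth: list[TruthRecord] = []
    transcripts: dict[str, str] = {}
    transcript_coords: dict[str, tuple[str, int, int, str]] = {}
    degradome: dict[str, dict[str, dict[int, int]]] = {
        lib: {} for lib in DEGRADOME_LIBRARIES
    }
    for t_idx, rec in enumerate(implants):
        contig, cycle, p1 = rec["contig"], rec["cycle"], rec["p1"]
        gseq = genome[contig]
        phased = [p1 + j * cycle for j in range(m)]
        for p in phased:
            plus = gseq[p - 1 : p - 1 + cycle]
            minus = revcomp(gseq[p - 3 : p - 3 + cycle])  # leftmost = p - 2
            for lib in lib_names:
                add_read(lib, plus, _lognormal_count(rng, config.phased_read_abundance))
                add_read(lib, minus, _lognormal_count(rng, config.phased_read_abundance))
        # transcript covering the precursor (plus strand)
        t_end_g = rec.get("site3_end", rec["region_end"]) + 20
        t_start_g = max(1, p1 - margin_up)
        t_end_g = min(len(gseq), t_end_g)
        tid = f"T{t_idx + 1:04d}"
        transcripts[tid] = gseq[t_start_g - 1 : t_end_g]
        transcript_coords[tid] = (contig, t_start_g, t_end_g, "+")
        for lib in DEGRADOME_LIBRARIES:
            posmap = degradome[lib].setdefault(tid, {})
            for g_cleav in rec["cleavages"]:
                local = g_cleav - t_start_g + 1
                posmap[local] = posmap.get(local, 0) + config.degradome_signal
        truth.append(
            TruthRecord(
                locus_id=f"truth_{t_idx + 1}",
                contig=contig,
                start=p1,
                end=rec["region_end"],
                cycle=cycle,
                strand_of_trigger_site="+",
                trigger_name=rec["trigger"],
                phased_positions=phased,
                locus_class=rec["class"],
                transcript_id=tid,
                transcript_start=t_start_g,
                transcript_end=t_end_g,
                tasiarf=rec.get("tasiarf"),
            )
        )

    # --- background reads ---------------------------------------------------
    n_background = int(round(config.background_read_density * config.genome_length / 1000))
    repeat_names = sorted(repeats)
    for _ in range(n_background):
        length = 21 if rng.integers(0, 2) == 0 else 24
        count = max(1, int(rng.poisson(config.background_abundance)))
        lib = lib_names[int(rng.integers(0, len(lib_names)))]
        if rng.random() < config.repeat_fraction:
            rep = repeats[repeat_names[int(rng.integers(0, len(repeat_names)))]]
            start = int(rng.integers(0, len(rep) - length))
            seq = rep[start : start + length]
        else:
            contig = contig_names[int(rng.integers(0, config.n_contigs))]
            start = int(rng.integers(0, contig_len - length))
            seq = genome[contig][start : start + length]
            if rng.integers(0, 2) == 1:
                seq = revcomp(seq)
        add_read(lib, seq, count)

    # --- degradome noise ----------------------------------------------------
    for lib in DEGRADOME_LIBRARIES:
        for tid in sorted(transcripts):
            tlen = len(transcripts[tid])
            n_noise = int(round(config.degradome_noise_density * tlen / 1000))
            posmap = degradome[lib].setdefault(tid, {})
            for _ in range(n_noise):
                pos = int(rng.integers(1, tlen + 1))
                posmap[pos] = posmap.get(pos, 0) + int(rng.poisson(2)) + 1

    return SimBundle(
        config=config,
        genome=genome,
        libraries=libraries,
        degradome=degradome,
        transcripts=transcripts,
        transcript_coords=transcript_coords,
        mirnas=mirnas,
        repeats=repeats,
        tasiarfs=tasiarfs,
        truth=truth,
    )
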