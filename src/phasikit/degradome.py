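"""Binding-site search and degradome (PARE) validation.

An sRNA binds its target antiparallel and (in plants) near-perfectly
complementary: sRNA position ``i`` pairs transcript position
``t_end - i + 1``.  AGO-guided slicing cuts the target opposite sRNA
positions 10/11, so the expected cleavage position is ``t_end - 9`` and a
degradome read whose 5' end falls opposite sRNA positions 9-11 (transcript
positions ``{t_end - 10, t_end - 9, t_end - 8}``) is a *valid read* — direct
sequencing evidence of slicing.

Two retention policies from the study are kept as named filters:

- ``trigger_rule``: >= 1 valid read in any profile OR mismatches < 4
  (used when hunting the miRNA trigger of a PHAS locus);
- ``target_rule``: (>= 1 valid read in any profile AND mismatches <= 4)
  OR mismatches == 0 (used for phasiRNA targets).

G:U wobble pairs count as mismatches by default; an exploratory flag can
down-weight them to 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import revcomp

VALID_READ_OFFSETS = (-10, -9, -8)  # relative to t_end: opposite sRNA 9..11
CLEAVAGE_OFFSET = -9  # opposite sRNA position 10


@dataclass
class BindingSite:
    srna_name: str
    srna_sequence: str
    transcript: str
    t_start: int  # 1-based inclusive
    t_end: int
    mismatches: float
    valid_reads: dict[str, int] = field(default_factory=dict)
    total_reads_at_site: int = 0
    category: str = ""

    @property
    def cleavage_pos(self) -> int:
        return self.t_end + CLEAVAGE_OFFSET

    @property
    def valid_window(self) -> tuple[int, int, int]:
        return tuple(self.t_end + off for off in VALID_READ_OFFSETS)  # type: ignore[return-value]


@dataclass
class DegradomeProfile:
    """5'-end read counts of one degradome library, per transcript."""

    library: str
    counts: dict[str, dict[int, int]] = field(default_factory=dict)

    def at(self, transcript: str, position: int) -> int:
        return self.counts.get(transcript, {}).get(position, 0)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def find_binding_sites(
    srna_name: str,
    srna_sequence: str,
    transcript_id: str,
    transcript_sequence: str,
    max_mismatches: float = 4,
    gu_half_weight: bool = False,
) -> list[BindingSite]:
    """All ungapped antiparallel alignments with <= ``max_mismatches``.

    Exhaustive over every start offset (no seed heuristic, no gaps); a
    transcript shorter than the sRNA yields an empty list.  The match is
    evaluated by comparing the sRNA's reverse complement against every
    transcript window; with ``gu_half_weight`` a G:U wobble (sRNA G opposite
    transcript U, or sRNA U opposite transcript G) costs 0.5 instead of 1.
    """
    L = len(srna_sequence)
    if not 18 <= L <= 26:
        raise ValueError(f"sRNA length {L} outside 18..26")
    T = len(transcript_sequence)
    if T < L:
        return []
    rc = _encode(revcomp(srna_sequence))
    t = _encode(transcript_sequence)
    win = np.lib.stride_tricks.sliding_window_view(t, L)
    mism = (win != rc).sum(axis=1).astype(float)
    if gu_half_weight:
        # in reverse-complement space: rc 'C' vs transcript 'T' is sRNA G:U;
        # rc 'A' vs transcript 'G' is sRNA U:G
        wobble = ((rc == ord("C")) & (win == ord("T"))) | (
            (rc == ord("A")) & (win == ord("G"))
        )
        mism -= 0.5 * wobble.sum(axis=1)
    sites = []
    for off in np.nonzero(mism <= max_mismatches)[0]:
        t_start = int(off) + 1
        sites.append(
            BindingSite(
                srna_name=srna_name,
                srna_sequence=srna_sequence,
                transcript=transcript_id,
                t_start=t_start,
                t_end=t_start + L - 1,
                mismatches=float(mism[off]) if gu_half_weight else int(mism[off]),
            )
        )
    return sites


def count_valid_reads(
    site: BindingSite, profiles: Iterable[DegradomeProfile]
) -> dict[str, int]:
    """Per-library counts of degradome reads with 5' end opposite sRNA
    positions 9-11; the site's ``valid_reads`` and totals are filled in."""
    window = site.valid_window
    valid: dict[str, int] = {}
    total = 0
    for profile in profiles:
        valid[profile.library] = sum(profile.at(site.transcript, p) for p in window)
        total += sum(profile.counts.get(site.transcript, {}).values())
    site.valid_reads = valid
    site.total_reads_at_site = total
    n_valid = sum(valid.values())
    if n_valid > 0 and site.mismatches < 4:
        site.category = "both"
    elif n_valid > 0:
        site.category = "valid_read_supported"
    elif site.mismatches < 4:
        site.category = "low_mismatch_only"
    return valid


def trigger_rule(mismatches: float, valid_reads: Mapping[str, int]) -> bool:
    """Retention rule for miRNA triggers: >=1 valid read OR < 4 mismatches."""
    return any(v >= 1 for v in valid_reads.values()) or mismatches < 4


def target_rule(mismatches: float, valid_reads: Mapping[str, int]) -> bool:
    """Retention rule for phasiRNA targets:
    (>=1 valid read AND <= 4 mismatches) OR 0 mismatches."""
    has_valid = any(v >= 1 for v in valid_reads.values())
    return (has_valid and mismatches <= 4) or mismatches == 0


def select_trigger_candidates(
    mirnas: Mapping[str, str],
    locus_records: Sequence[Mapping[str, object]],
    profiles: Sequence[DegradomeProfile],
    max_mismatches: float = 5,
    gu_half_weight: bool = False,
) -> pd.DataFrame:
    """Trigger table: best binding site of every miRNA on every locus.

    Each entry of ``locus_records`` describes one PHAS locus used as target
    cDNA: keys ``name``, ``sequence`` (plus strand), ``start`` (genomic start
    of the sequence), ``anchor`` (register), ``cycle``, ``phased_positions``
    (genomic, in-register occupied), and optionally ``profile`` (a per-locus
    degradome map {library: {local position: count}} lifted onto the locus).
    Both strands of the locus are searched (loci are unstranded intervals).
    Rows are retained iff the trigger rule holds; ``distance_to_register`` is
    the distance from the inferred cleavage position to the nearest
    in-register phased position, 0 when the cleavage sets the phase.
    """
    rows = []
    for locus in locus_records:
        name = str(locus["name"])
        seq = str(locus["sequence"])
        g_start = int(locus["start"])
        cycle = int(locus["cycle"])
        phased = sorted(int(p) for p in locus.get("phased_positions", []))
        if locus.get("profile"):
            local_profiles = [
                DegradomeProfile(lib, {name: dict(posmap)})
                for lib, posmap in sorted(dict(locus["profile"]).items())  # type: ignore[index]
            ]
        else:
            local_profiles = list(profiles)
        lib_names = [p.library for p in local_profiles]
        strand_seqs = {"+": seq, "-": revcomp(seq)}
        for mir_name in sorted(mirnas):
            best_per_strand = []
            for strand, sseq in strand_seqs.items():
                sites = find_binding_sites(
                    mir_name, mirnas[mir_name], name, sseq, max_mismatches, gu_half_weight
                )
                for s in sites:
                    # degradome counts are recorded on the plus strand of the
                    # locus; minus-strand sites see zero valid reads
                    count_valid_reads(s, local_profiles if strand == "+" else [])
                    best_per_strand.append((strand, s))
            if not best_per_strand:
                continue
            strand, site = min(
                best_per_strand,
                key=lambda t: (
                    t[1].mismatches,
                    -sum(t[1].valid_reads.values()),
                    t[0] != "+",
                    t[1].t_start,
                ),
            )
            if strand == "+":
                g_cleavage = g_start + site.cleavage_pos - 1
            else:
                g_cleavage = g_start + len(seq) - site.cleavage_pos
            distance = min((abs(g_cleavage - p) for p in phased), default=-1)
            offset = (g_cleavage - int(locus["anchor"])) % cycle
            valid = {f"valid_{lib}": site.valid_reads.get(lib, 0) for lib in lib_names}
            retained = trigger_rule(site.mismatches, site.valid_reads)
            rows.append(
                {
                    "mirna": mir_name,
                    "locus": name,
                    "strand": strand,
                    "t_start": site.t_start,
                    "t_end": site.t_end,
                    "mismatches": site.mismatches,
                    **valid,
                    "total_valid_reads": sum(site.valid_reads.values()),
                    "cleavage_genomic": g_cleavage,
                    "distance_to_register": distance,
                    "register_offset": offset,
                    "retained": retained,
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df[df["retained"]].reset_index(drop=True)
    return df


def select_phasirna_targets(
    phasirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    profiles: Sequence[DegradomeProfile],
    max_mismatches: float = 4,
    gu_half_weight: bool = False,
) -> pd.DataFrame:
    """Target table for phasiRNAs against a transcript set.

    Every site with <= ``max_mismatches`` is evaluated; a row is kept iff the
    target rule holds.  Both the target-rule and trigger-rule flags are
    reported (the two retention policies differ and are kept apart).
    Identical phasiRNA sequences are searched once and expanded to all names.
    """
    by_seq: dict[str, list[str]] = {}
    for name in sorted(phasirnas):
        by_seq.setdefault(phasirnas[name], []).append(name)
    rows = []
    for seq in sorted(by_seq):
        for tid in sorted(transcripts):
            for site in find_binding_sites(
                by_seq[seq][0], seq, tid, transcripts[tid], max_mismatches, gu_half_weight
            ):
                count_valid_reads(site, profiles)
                keep_target = target_rule(site.mismatches, site.valid_reads)
                keep_trigger = trigger_rule(site.mismatches, site.valid_reads)
                if not keep_target:
                    continue
                for name in by_seq[seq]:
                    rows.append(
                        {
                            "phasirna": name,
                            "sequence": seq,
                            "transcript": tid,
                            "t_start": site.t_start,
                            "t_end": site.t_end,
                            "mismatches": site.mismatches,
                            "cleavage_pos": site.cleavage_pos,
                            **{
                                f"valid_{p.library}": site.valid_reads.get(p.library, 0)
                                for p in profiles
                            },
                            "category": site.category,
                            "target_rule": keep_target,
                            "trigger_rule": keep_trigger,
                        }
                    )
    return pd.DataFrame(rows)


def tplot_data(
    site: BindingSite, profile: DegradomeProfile, transcript_length: int
) -> pd.DataFrame:
    """Per-position degradome counts along the transcript with the site and
    expected cleavage position annotated (the data behind a T-plot)."""
    counts = profile.counts.get(site.transcript, {})
    positions = np.arange(1, transcript_length + 1)
    values = np.array([counts.get(int(p), 0) for p in positions])
    df = pd.DataFrame({"position": positions, "count": values})
    df["in_site"] = (df["position"] >= site.t_start) & (df["position"] <= site.t_end)
    df["is_cleavage"] = df["position"] == site.cleavage_pos
    return df


def plot_tplot(site: BindingSite, profile: DegradomeProfile, transcript_length: int, path):
    """Optional thin plotting layer (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = tplot_data(site, profile, transcript_length)
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.vlines(df["position"], 0, df["count"], color="grey", lw=0.8)
    ax.axvspan(site.t_start, site.t_end, alpha=0.2, color="orange", label="binding site")
    ax.axvline(site.cleavage_pos, color="red", lw=1.2, label="expected cleavage")
    ax.set_xlabel(f"{site.transcript} position (nt)")
    ax.set_ylabel(f"{profile.library} degradome reads")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
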