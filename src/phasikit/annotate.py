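"""TAS3-style annotation, locus annotation joins, cis/trans target
classification, shared-phasiRNA reporting, and network export.

TAS3 loci are found by their conserved products: a tasiARF aligned to the
genome with at most two mismatches marks a candidate, the ±250-nt flanks are
extracted, and the dual miR390 architecture (one complementary site on each
side of the tasiARF, the "two-hit" trigger model) labels the candidate
TAS3-like.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .degradome import BindingSite, DegradomeProfile, count_valid_reads, find_binding_sites
from .io_formats import revcomp
from .loci import PhasLocus

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 250
DEFAULT_TASIARF_MM = 2


@dataclass
class TasiArfMatch:
    tasiarf: str
    contig: str
    match_start: int
    match_end: int
    strand: str
    mismatches: int
    flank_start: int
    flank_end: int
    mir390_sites_5p: list[BindingSite] = field(default_factory=list)
    mir390_sites_3p: list[BindingSite] = field(default_factory=list)
    classification: str = "unclassified"
    locus_link: str | None = None


def _mismatch_profile(genome: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Mismatch count of ``query`` at every offset of ``genome`` (ungapped)."""
    L = query.size
    win = np.lib.stride_tricks.sliding_window_view(genome, L)
    return (win != query).sum(axis=1)


def find_tasiarf_matches(
    tasiarfs: Mapping[str, str],
    genome: Mapping[str, str],
    max_mismatches: int = DEFAULT_TASIARF_MM,
    flank: int = DEFAULT_FLANK,
) -> list[TasiArfMatch]:
    """All ungapped genome matches of each tasiARF with <= ``max_mismatches``
    on either strand, with ±``flank``-nt flanks clamped to the contig."""
    out: list[TasiArfMatch] = []
    for contig in sorted(genome):
        gseq = genome[contig]
        g = np.frombuffer(gseq.encode("ascii"), dtype=np.uint8)
        for name in sorted(tasiarfs):
            seq = tasiarfs[name]
            if not 20 <= len(seq) <= 22:
                raise ValueError(f"tasiARF {name} length {len(seq)} outside 20..22")
            if g.size < len(seq):
                continue
            for strand, query in (("+", seq), ("-", revcomp(seq))):
                q = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
                mm = _mismatch_profile(g, q)
                for off in np.nonzero(mm <= max_mismatches)[0]:
                    start = int(off) + 1
                    end = start + len(seq) - 1
                    out.append(
                        TasiArfMatch(
                            tasiarf=name,
                            contig=contig,
                            match_start=start,
                            match_end=end,
                            strand=strand,
                            mismatches=int(mm[off]),
                            flank_start=max(1, start - flank),
                            flank_end=min(len(gseq), end + flank),
                        )
                    )
    out.sort(key=lambda m: (m.contig, m.match_start, m.strand, m.tasiarf))
    return out


def classify_tas3(
    match: TasiArfMatch,
    genome: Mapping[str, str],
    mir390s: Mapping[str, str],
    profiles: Sequence[DegradomeProfile] = (),
    max_mismatches: float = 4,
) -> TasiArfMatch:
    """Predict miR390 complementary sites on the flanks and classify.

    Sites are searched on both strands of the flank sequence; a site on each
    side of the tasiARF (5'/3' defined relative to the tasiARF match strand)
    gives the TAS3-like label, a site on one side only gives "single-site",
    none leaves the match unclassified.  Cleavability (valid degradome reads)
    is recorded per site when profiles are supplied.
    """
    flank_seq = genome[match.contig][match.flank_start - 1 : match.flank_end]
    sites: list[BindingSite] = []
    tid = f"{match.contig}:{match.flank_start}-{match.flank_end}"
    for mir_name in sorted(mir390s):
        for strand, seq in (("+", flank_seq), ("-", revcomp(flank_seq))):
            for site in find_binding_sites(
                mir_name, mir390s[mir_name], tid, seq, max_mismatches
            ):
                if strand == "-":  # map back to plus-strand flank coordinates
                    L = len(flank_seq)
                    site.t_start, site.t_end = L - site.t_end + 1, L - site.t_start + 1
                count_valid_reads(site, profiles)
                sites.append(site)
    # genomic coordinates of the tasiARF within the flank
    arf_lo = match.match_start - match.flank_start + 1
    arf_hi = match.match_end - match.flank_start + 1
    upstream = [s for s in sites if s.t_end < arf_lo]
    downstream = [s for s in sites if s.t_start > arf_hi]
    if match.strand == "+":
        match.mir390_sites_5p, match.mir390_sites_3p = upstream, downstream
    else:
        match.mir390_sites_5p, match.mir390_sites_3p = downstream, upstream
    if match.mir390_sites_5p and match.mir390_sites_3p:
        match.classification = "TAS3-like"
    elif match.mir390_sites_5p or match.mir390_sites_3p:
        match.classification = "single-site"
    else:
        match.classification = "unclassified"
    return match


def link_matches_to_loci(
    matches: Iterable[TasiArfMatch], loci: Sequence[PhasLocus]
) -> None:
    """Attach the name of an overlapping called locus to each match."""
    trees: dict[str, IntervalTree] = {}
    for locus in loci:
        trees.setdefault(locus.contig, IntervalTree()).addi(
            locus.start, locus.end + 1, locus.name
        )
    for m in matches:
        tree = trees.get(m.contig)
        if tree:
            hits = sorted(iv.data for iv in tree.overlap(m.match_start, m.match_end + 1))
            m.locus_link = hits[0] if hits else None


def tas3_report(matches: Sequence[TasiArfMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tasiarf": m.tasiarf, "contig": m.contig,
                "match_start": m.match_start, "match_end": m.match_end,
                "strand": m.strand, "mismatches": m.mismatches,
                "flank_start": m.flank_start, "flank_end": m.flank_end,
                "n_sites_5p": len(m.mir390_sites_5p),
                "n_sites_3p": len(m.mir390_sites_3p),
                "classification": m.classification,
                "locus_link": m.locus_link or "",
            }
            for m in matches
        ]
    )


def classify_cis_trans(
    targets: pd.DataFrame,
    loci: Sequence[PhasLocus],
    transcript_coords: Mapping[str, tuple[str, int, int, str]],
    locus_families: Mapping[str, str] | None = None,
    transcript_families: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Label each target row cis / same_family / other.

    cis: the target transcript overlaps the phasiRNA's generating locus
    (identified from the phasiRNA name prefix).  same_family: locus host gene
    and target share a family label.  Precedence cis > same_family > other;
    missing annotation degrades everything non-cis to other with a warning.
    The result is independent of input row order.
    """
    if targets.empty:
        out = targets.copy()
        out["target_class"] = pd.Series(dtype=str)
        return out
    locus_by_name = {l.name: l for l in loci}
    if locus_families is None or transcript_families is None:
        logger.warning("no family annotation: non-cis targets labeled 'other'")
        locus_families = locus_families or {}
        transcript_families = transcript_families or {}

    def classify(row: pd.Series) -> str:
        locus_name = str(row["phasirna"]).rsplit("_siR", 1)[0]
        locus = locus_by_name.get(locus_name)
        coords = transcript_coords.get(str(row["transcript"]))
        if locus is not None and coords is not None:
            contig, start, end, _ = coords
            if contig == locus.contig and start <= locus.end and end >= locus.start:
                return "cis"
        fam_locus = locus_families.get(locus_name)
        fam_target = transcript_families.get(str(row["transcript"]))
        if fam_locus and fam_target and fam_locus == fam_target:
            return "same_family"
        return "other"

    out = targets.copy()
    out["target_class"] = out.apply(classify, axis=1)
    return out


def shared_phasirna_report(loci: Sequence[PhasLocus]) -> pd.DataFrame:
    """phasiRNA sequences generated by more than one locus, with the
    generating loci listed per sequence."""
    by_seq: dict[str, dict[str, list[str]]] = {}
    for locus in loci:
        for p in locus.phasirnas:
            entry = by_seq.setdefault(p.sequence, {"loci": [], "names": []})
            if locus.name not in entry["loci"]:
                entry["loci"].append(locus.name)
            entry["names"].append(p.name)
    rows = [
        {
            "sequence": seq,
            "n_loci": len(entry["loci"]),
            "loci": ",".join(sorted(entry["loci"])),
            "phasirna_names": ",".join(sorted(entry["names"])),
        }
        for seq, entry in sorted(by_seq.items())
        if len(entry["loci"]) > 1
    ]
    return pd.DataFrame(rows)


def export_network(
    loci: Sequence[PhasLocus], targets: pd.DataFrame
) -> pd.DataFrame:
    """Edge table (source, interaction, sink, target_class) for network
    tools: generates-edges locus -> phasiRNA, targets-edges phasiRNA -> gene.
    Deterministic row order."""
    rows = []
    for locus in sorted(loci, key=lambda l: l.name):
        for p in locus.phasirnas:
            rows.append(
                {"source": locus.name, "interaction": "generates",
                 "sink": p.name, "target_class": ""}
            )
    if not targets.empty:
        cols = ["phasirna", "transcript"]
        tclass = targets["target_class"] if "target_class" in targets else ""
        edges = targets[cols].assign(target_class=tclass)
        edges = edges.drop_duplicates().sort_values(cols, kind="stable")
        for _, r in edges.iterrows():
            rows.append(
                {"source": r["phasirna"], "interaction": "targets",
                 "sink": r["transcript"], "target_class": r["target_class"]}
            )
    return pd.DataFrame(rows, columns=["source", "interaction", "sink", "target_class"])


def annotate_loci(loci: Sequence[PhasLocus], annotation: pd.DataFrame) -> pd.DataFrame:
    """Interval-overlap join of loci with a user-supplied annotation table.

    ``annotation`` needs columns contig, start, end, label, family.  All
    overlaps are kept (multi-hits flagged); unmatched loci are labeled
    "unannotated".
    """
    required = {"contig", "start", "end", "label", "family"}
    if not required <= set(annotation.columns):
        raise ValueError(f"annotation table must have columns {sorted(required)}")
    trees: dict[str, IntervalTree] = {}
    for _, r in annotation.iterrows():
        trees.setdefault(str(r["contig"]), IntervalTree()).addi(
            int(r["start"]), int(r["end"]) + 1, (str(r["label"]), str(r["family"]))
        )
    rows = []
    for locus in loci:
        tree = trees.get(locus.contig)
        hits = sorted(iv.data for iv in tree.overlap(locus.start, locus.end + 1)) if tree else []
        if not hits:
            rows.append(
                {"name": locus.name, "label": "unannotated", "family": "",
                 "multi_hit": False}
            )
        else:
            for label, family in hits:
                rows.append(
                    {"name": locus.name, "label": label, "family": family,
                     "multi_hit": len(hits) > 1}
                )
    return pd.DataFrame(rows)
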