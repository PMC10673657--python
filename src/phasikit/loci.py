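"""From significant windows to extended, merged, FDR-corrected, named PHAS
loci, and extraction of their phasiRNAs.

The calling rule: windows with raw P < 0.05 are extended by 100 bp on both
sides, overlapping extensions are merged keeping the smallest member P-value,
merged intervals are Benjamini-Hochberg corrected within each cycle class,
and an interval is reported as a PHAS locus iff its maximum phase score
exceeds 5 (strictly) and its corrected P-value is below 0.05.  A
permutation-based false-positive rate is attached as a report column, not a
filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io_formats import ReadPlacement
from .phasing import (
    ContigOccupancy,
    PhaseParams,
    PhaseWindow,
    aggregate_occupancy,
    effective_position,
    hypergeometric_pvalue,
    window_counts,
)

DEFAULT_EXTEND_BP = 100
DEFAULT_P_WINDOW = 0.05
DEFAULT_SCORE_MIN = 5.0
DEFAULT_FDR = 0.05


@dataclass
class Interval:
    """A (possibly merged) candidate interval carried between locus stages."""

    contig: str
    start: int
    end: int
    cycle: int
    p_value: float
    anchor: int  # register-defining anchor of the minimal-p member window
    max_phase_score: float
    p_adjusted: float | None = None
    fpr: float | None = None


@dataclass
class PhasiRNA:
    name: str
    sequence: str
    position: int  # effective position
    strand: str
    counts: dict[str, int]
    register_name: str = ""  # D-notation alternative, e.g. PHAS_c1_1_D8(+)


@dataclass
class PhasLocus:
    name: str
    contig: str
    start: int
    end: int
    cycle: int
    p_value: float
    p_adjusted: float
    max_phase_score: float
    anchor: int
    fpr: float | None = None
    phasirnas: list[PhasiRNA] = field(default_factory=list)


def extend_windows(
    windows: Iterable[PhaseWindow],
    contig_lengths: Mapping[str, int],
    p_max: float = DEFAULT_P_WINDOW,
    extend_bp: int = DEFAULT_EXTEND_BP,
) -> list[Interval]:
    """Extend windows with P < ``p_max`` by ``extend_bp`` nt, clamped to the
    contig; windows at or above the gate are not passed on."""
    out = []
    for w in windows:
        if w.p_value >= p_max:
            continue
        clen = contig_lengths[w.contig]
        out.append(
            Interval(
                contig=w.contig,
                start=max(1, w.start - extend_bp),
                end=min(clen, w.end + extend_bp),
                cycle=w.cycle,
                p_value=w.p_value,
                anchor=w.anchor,
                max_phase_score=w.max_phase_score,
            )
        )
    out.sort(key=lambda iv: (iv.contig, iv.start, iv.end))
    return out


def merge_windows(intervals: Iterable[Interval]) -> list[Interval]:
    """Transitive overlap-merge (same contig and cycle, >= 1 nt shared).

    The representative P-value is the minimum over members; the register
    anchor follows the minimal-p member (ties: smaller coordinate); the score
    is the members' maximum.  Idempotent.
    """
    by_key: dict[tuple[str, int], list[Interval]] = {}
    for iv in intervals:
        by_key.setdefault((iv.contig, iv.cycle), []).append(iv)
    merged: list[Interval] = []
    for key in sorted(by_key):
        ivs = sorted(by_key[key], key=lambda iv: (iv.start, iv.end))
        current = replace(ivs[0])
        for iv in ivs[1:]:
            if iv.start <= current.end:  # 1-based inclusive overlap
                current.end = max(current.end, iv.end)
                if (iv.p_value, iv.anchor) < (current.p_value, current.anchor):
                    current.p_value = iv.p_value
                    current.anchor = iv.anchor
                current.max_phase_score = max(current.max_phase_score, iv.max_phase_score)
            else:
                merged.append(current)
                current = replace(iv)
        merged.append(current)
    merged.sort(key=lambda iv: (iv.contig, iv.start, iv.end, iv.cycle))
    return merged


def adjust_pvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values (monotone in rank)."""
    if len(pvalues) == 0:
        raise ValueError("adjust_pvalues requires at least one interval")
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def adjust_intervals(
    intervals: list[Interval],
    reference_pvalues: Mapping[int, Sequence[float]] | None = None,
) -> list[Interval]:
    """BH adjustment applied separately to each cycle class, in place.

    By default the multiplicity universe is the merged intervals themselves.
    When ``reference_pvalues`` maps cycle -> the raw P-values of *all*
    candidate windows scanned, each interval inherits the BH-adjusted value
    of its minimal-p member within that full universe.  The scan tests every
    candidate window, so correcting only the intervals that already survived
    the raw p < 0.05 extension gate would understate the multiplicity;
    the pipeline therefore passes the full window universe here.
    """
    for cycle in sorted({iv.cycle for iv in intervals}):
        group = [iv for iv in intervals if iv.cycle == cycle]
        if reference_pvalues is not None and cycle in reference_pvalues:
            ref = np.asarray(reference_pvalues[cycle], dtype=float)
        else:
            ref = np.asarray([iv.p_value for iv in group], dtype=float)
        adjusted = adjust_pvalues(ref)
        order = np.argsort(ref, kind="stable")
        sorted_p, sorted_adj = ref[order], adjusted[order]
        for iv in group:
            idx = int(np.searchsorted(sorted_p, iv.p_value, side="left"))
            idx = min(idx, sorted_p.size - 1)
            iv.p_adjusted = float(sorted_adj[idx])
    return intervals


def _best_window_p(
    positions: np.ndarray, abundance: np.ndarray, start: int, end: int, params: PhaseParams
) -> float:
    """Minimal window P over anchors inside [start, end] for one slot set."""
    occ = ContigOccupancy(
        positions=positions, strands=np.array(["+"] * positions.size), abundance=abundance
    )
    W = params.window
    anchors = [int(p) for p in occ.unique_positions if int(p) + W - 1 <= end]
    best = 1.0
    if anchors:
        for anchor in anchors:
            n, k, _, _ = window_counts(occ, anchor, anchor + W - 1, anchor, params.cycle)
            best = min(best, hypergeometric_pvalue(n, k, params))
    else:
        # interval tail shorter than W: evaluate one right-aligned window
        lo = max(start, end - W + 1)
        for anchor in (int(p) for p in occ.unique_positions):
            n, k, _, _ = window_counts(occ, lo, end, anchor, params.cycle)
            best = min(best, hypergeometric_pvalue(n, min(k, n), params))
    return best


def estimate_fpr(
    interval: Interval,
    placements: Iterable[ReadPlacement],
    params: PhaseParams,
    n_permutations: int = 1000,
    seed: int = 0,
    observed_p: float | None = None,
) -> float:
    """Permutation false-positive rate of a merged interval.

    Slot effective positions are resampled uniformly within the interval
    (abundance multiplicities preserved, strands redrawn); the FPR is the
    fraction of permutations whose best window P is <= the observed
    representative P.  Seeded and reproducible.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    if observed_p is None:
        observed_p = interval.p_value
    occ = aggregate_occupancy(
        (pl for pl in placements if pl.contig == interval.contig), interval.cycle
    )
    if interval.contig not in occ:
        return 1.0
    c_occ = occ[interval.contig]
    mask = (c_occ.positions >= interval.start) & (c_occ.positions <= interval.end)
    abundance = c_occ.abundance[mask]
    n_slots = int(mask.sum())
    if n_slots == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    hits = 0
    span = interval.end - interval.start + 1
    for _ in range(n_permutations):
        pos = rng.integers(0, span, size=n_slots) + interval.start
        strand = rng.integers(0, 2, size=n_slots)
        # merge collisions on (position, strand)
        key = pos * 2 + strand
        uniq, inv = np.unique(key, return_inverse=True)
        ab = np.zeros(uniq.size)
        np.add.at(ab, inv, abundance)
        perm_pos = (uniq // 2).astype(np.int64)
        order = np.argsort(perm_pos, kind="stable")
        best = _best_window_p(perm_pos[order], ab[order], interval.start, interval.end, params)
        if best <= observed_p:
            hits += 1
    return hits / n_permutations


def call_loci(
    intervals: Iterable[Interval],
    score_min: float = DEFAULT_SCORE_MIN,
    fdr: float = DEFAULT_FDR,
    name_prefix: str = "PHAS",
) -> list[PhasLocus]:
    """Report intervals with max phase score > ``score_min`` (strict) and
    adjusted P < ``fdr`` as named loci.

    Names are ``PHAS_<contig>_<serial>`` with serials consecutive per contig
    in coordinate order — a pure function of (contig order, coordinates).
    """
    called = [
        iv
        for iv in intervals
        if iv.p_adjusted is not None
        and iv.max_phase_score > score_min
        and iv.p_adjusted < fdr
    ]
    called.sort(key=lambda iv: (iv.contig, iv.start, iv.end, iv.cycle))
    loci: list[PhasLocus] = []
    serial: dict[str, int] = {}
    for iv in called:
        serial[iv.contig] = serial.get(iv.contig, 0) + 1
        loci.append(
            PhasLocus(
                name=f"{name_prefix}_{iv.contig}_{serial[iv.contig]}",
                contig=iv.contig,
                start=iv.start,
                end=iv.end,
                cycle=iv.cycle,
                p_value=iv.p_value,
                p_adjusted=float(iv.p_adjusted),
                max_phase_score=iv.max_phase_score,
                anchor=iv.anchor,
                fpr=iv.fpr,
            )
        )
    return loci


def extract_phasirnas(locus: PhasLocus, placements: Iterable[ReadPlacement]) -> list[PhasiRNA]:
    """One phasiRNA per occupied in-register (position, strand) slot of the
    locus, numbered ``siR1..`` densely in 5'->3' coordinate order.

    The register is set by the locus anchor; reads of length != cycle are
    ignored.  The D-notation alternative (register index relative to the
    anchor, with strand) is attached as ``register_name``.
    """
    found: dict[tuple[int, str], ReadPlacement] = {}
    for pl in placements:
        if pl.contig != locus.contig or pl.length != locus.cycle:
            continue
        eff = effective_position(pl)
        if eff < locus.start or eff > locus.end:
            continue
        if (eff - locus.anchor) % locus.cycle != 0:
            continue
        found.setdefault((eff, pl.strand), pl)
    ordered = sorted(found, key=lambda t: (t[0], t[1]))
    out = []
    for i, (pos, strand) in enumerate(ordered, start=1):
        pl = found[(pos, strand)]
        d_index = (pos - locus.anchor) // locus.cycle + 1
        out.append(
            PhasiRNA(
                name=f"{locus.name}_siR{i}",
                sequence=pl.read.sequence,
                position=pos,
                strand=strand,
                counts=dict(pl.read.counts),
                register_name=f"{locus.name}_D{d_index}({strand})",
            )
        )
    return out


def phasirna_count_matrix(loci: Sequence[PhasLocus]) -> pd.DataFrame:
    """phasiRNA x library count matrix (rows ordered by locus, serial)."""
    rows, names = [], []
    libraries: set[str] = set()
    for locus in loci:
        for p in locus.phasirnas:
            libraries.update(p.counts)
    lib_order = sorted(libraries)
    for locus in loci:
        for p in locus.phasirnas:
            names.append(p.name)
            rows.append([p.counts.get(lib, 0) for lib in lib_order])
    return pd.DataFrame(rows, index=names, columns=lib_order)


def loci_to_frame(loci: Sequence[PhasLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": l.name, "contig": l.contig, "start": l.start, "end": l.end,
                "cycle": l.cycle, "p_value": l.p_value, "p_adjusted": l.p_adjusted,
                "max_phase_score": l.max_phase_score, "anchor": l.anchor,
                "fpr": l.fpr if l.fpr is not None else float("nan"),
                "n_phasirnas": len(l.phasirnas),
            }
            for l in loci
        ]
    )


def loci_gff3_rows(loci: Sequence[PhasLocus]) -> list[dict[str, object]]:
    rows: list[dict[str, object]] = []
    for l in loci:
        rows.append(
            {
                "contig": l.contig, "type": "siRNA_locus", "start": l.start,
                "end": l.end, "score": f"{l.max_phase_score:.3f}", "strand": ".",
                "attributes": f"ID={l.name};cycle={l.cycle};p_adjusted={l.p_adjusted:.3g}",
            }
        )
        for p in l.phasirnas:
            rows.append(
                {
                    "contig": l.contig, "type": "siRNA", "start": p.position,
                    "end": p.position + l.cycle - 1, "strand": p.strand,
                    "attributes": f"ID={p.name};Parent={l.name}",
                }
            )
    return rows
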