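"""Phase-register statistics for PHAS locus detection.

phasiRNAs are diced from a double-stranded precursor in head-to-tail
increments of the cycle length ``c`` (21 or 24 nt), so their 5' ends fall in
a single congruence class (the *phase register*) modulo ``c``.  Because the
duplex intermediates carry 2-nt 3' overhangs, a minus-strand phasiRNA that is
the exact duplex partner of a plus-strand read starting at ``p`` has leftmost
genomic coordinate ``p - 2``; antisense reads therefore join the register of
the sense strand through a two-nucleotide positive offset applied to their
leftmost coordinate (the *effective position*).

Detection scans fixed windows of ``W = 10 c`` nt (210 for 21-nt scans, 240
for 24-nt scans).  Within a window the occupancy universe is the ``N = 2 W``
(position, strand) slots; ``K = 2 W / c = 20`` of them sit in the register
defined by the window anchor.  With ``n`` occupied slots of which ``k`` are
in-register, the window P-value is the exact upper tail
``P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``.

Each genomic position additionally receives a phase score

    score = (k - 2) * ln(1 + 10 * P / (1 + U))   for k >= 3, else 0

where ``P``/``U`` sum read abundance at in-register / out-of-register
effective positions inside a window of width ``W`` centred on the scored
position, and ``k`` counts distinct occupied in-register slots there.  The
score rewards windows whose abundance is concentrated in one register and is
zero without at least three distinct in-register positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import ReadPlacement

ANTISENSE_OFFSET = 2  # nt; 2-nt 3' overhang duplex geometry


@dataclass(frozen=True)
class PhaseParams:
    """Parameters of one phasing scan.

    ``cycle`` is the phasiRNA length class (21 or 24 nt).  ``window_cycles``
    is the number of cycles per scan window (10 in the standard analysis,
    giving 210/240-nt windows); smaller values are useful for exhaustive
    miniature oracles.
    """

    cycle: int = 21
    window_cycles: int = 10
    min_k: int = 3
    score_formula: str = "howell_log"  # (k-2)*ln(1 + 10P/(1+U))
    test_formula: str = "chen_hypergeometric"  # upper tail, N=2W, K=2W/c

    def __post_init__(self) -> None:
        if self.cycle < 2 or self.window_cycles < 1:
            raise ValueError("cycle >= 2 and window_cycles >= 1 required")

    @property
    def window(self) -> int:
        """W: scan window width in nt."""
        return self.cycle * self.window_cycles

    @property
    def register_positions(self) -> int:
        """K: in-register occupancy slots in a window (both strands)."""
        return 2 * self.window_cycles

    @property
    def total_positions(self) -> int:
        """N: occupancy slots in a window (positions x strands)."""
        return 2 * self.window


@dataclass
class PhaseWindow:
    """A candidate window with its occupancy counts and statistics."""

    contig: str
    start: int  # == anchor
    cycle: int
    n: int
    k: int
    p_value: float
    max_phase_score: float
    window: int

    @property
    def end(self) -> int:
        return self.start + self.window - 1

    @property
    def anchor(self) -> int:
        return self.start


@dataclass
class PositionScore:
    contig: str
    position: int
    cycle: int
    P: float
    U: float
    k: int
    score: float


def effective_position(placement: ReadPlacement) -> int:
    """Phase coordinate of a placement: start, plus 2 nt on the minus strand.

    A perfect duplex partner of a plus-strand read at ``p`` spans
    ``[p - 2, p + c - 3]`` on the minus strand and thus maps back to
    effective position ``p``, joining the sense register.
    """
    if placement.strand == "+":
        return placement.start
    return placement.start + ANTISENSE_OFFSET


def hypergeometric_pvalue_exact(n: int, k: int, params: PhaseParams) -> Fraction:
    """Exact upper-tail P(X >= k), X ~ Hypergeom(N, K, n), as a Fraction."""
    N, K = params.total_positions, params.register_positions
    if k < 0 or k > n or n > N:
        raise ValueError(f"invalid occupancy n={n}, k={k} for N={N}")
    if k == 0:
        return Fraction(1)
    total = math.comb(N, n)
    tail = sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, min(n, K) + 1))
    return Fraction(tail, total)


def hypergeometric_pvalue(n: int, k: int, params: PhaseParams) -> float:
    """Float view of :func:`hypergeometric_pvalue_exact`."""
    return float(hypergeometric_pvalue_exact(n, k, params))


def phase_score(P: float, U: float, k: int, min_k: int = 3) -> float:
    """Phase score (k-2)*ln(1 + 10P/(1+U)); zero below the support threshold."""
    if P < 0 or U < 0 or k < 0:
        raise ValueError("P, U, k must be non-negative")
    if k < min_k:
        return 0.0
    return (k - 2) * math.log1p(10.0 * P / (1.0 + U))


# ---------------------------------------------------------------------------
# occupancy aggregation
# ---------------------------------------------------------------------------

@dataclass
class ContigOccupancy:
    """Occupancy slots of one contig, sorted by effective position.

    One slot per distinct (effective position, strand); ``abundance`` is the
    summed total read count at the slot (multi-mapping reads counted at every
    placement).
    """

    positions: np.ndarray  # int64, sorted (ties: '+' before '-')
    strands: np.ndarray  # '+'/'-' per slot
    abundance: np.ndarray  # float64 per slot
    unique_positions: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.unique_positions = np.unique(self.positions)


def aggregate_occupancy(
    placements: Iterable[ReadPlacement], cycle: int, unique_reads_only: bool = False
) -> dict[str, ContigOccupancy]:
    """Pool placements of length ``cycle`` into per-contig occupancy slots.

    Reads of any other length are excluded from both counts and abundances.
    With ``unique_reads_only`` each distinct read contributes 1 instead of
    its total library count.
    """
    slots: dict[str, dict[tuple[int, str], float]] = {}
    for pl in placements:
        if pl.length != cycle:
            continue
        eff = effective_position(pl)
        contig = slots.setdefault(pl.contig, {})
        key = (eff, pl.strand)
        weight = 1.0 if unique_reads_only else float(pl.read.total_count)
        contig[key] = contig.get(key, 0.0) + weight
    out: dict[str, ContigOccupancy] = {}
    for contig in sorted(slots):
        keys = sorted(slots[contig], key=lambda t: (t[0], t[1]))
        out[contig] = ContigOccupancy(
            positions=np.array([p for p, _ in keys], dtype=np.int64),
            strands=np.array([s for _, s in keys]),
            abundance=np.array([slots[contig][key] for key in keys], dtype=np.float64),
        )
    return out


def window_counts(
    occ: ContigOccupancy, start: int, end: int, anchor: int, cycle: int
) -> tuple[int, int, float, float]:
    """(n, k, P, U) over slots with effective position in [start, end].

    ``k``/``P`` cover slots congruent to ``anchor`` modulo ``cycle``;
    ``n``/``U`` complete them.
    """
    lo = np.searchsorted(occ.positions, start, side="left")
    hi = np.searchsorted(occ.positions, end, side="right")
    pos = occ.positions[lo:hi]
    ab = occ.abundance[lo:hi]
    in_reg = (pos - anchor) % cycle == 0
    n = int(pos.size)
    k = int(in_reg.sum())
    P = float(ab[in_reg].sum())
    U = float(ab[~in_reg].sum())
    return n, k, P, U


def position_score(
    occ: ContigOccupancy, position: int, params: PhaseParams, contig_length: int
) -> PositionScore:
    """Phase score of one genomic position (window centred, edge-truncated)."""
    W = params.window
    half = W // 2
    lo = max(1, position - half)
    hi = min(contig_length, lo + W - 1)
    lo = max(1, hi - W + 1)
    _, k, P, U = window_counts(occ, lo, hi, position, params.cycle)
    return PositionScore(
        contig="", position=position, cycle=params.cycle, P=P, U=U, k=k,
        score=phase_score(P, U, k, params.min_k),
    )


def scan_genome(
    placements: Iterable[ReadPlacement],
    params: PhaseParams,
    contig_lengths: Mapping[str, int],
    unique_reads_only: bool = False,
) -> list[PhaseWindow]:
    """Scan all contigs: one candidate window anchored at every occupied
    effective position.

    The window is ``[anchor, anchor + W - 1]`` with the register defined by
    the anchor; windows overlapping the contig end are dropped.  A
    significant register necessarily contains a read at its anchor, so
    anchoring at occupied positions gives the same candidate set as scanning
    every nucleotide, at far lower cost.
    """
    occupancy = aggregate_occupancy(placements, params.cycle, unique_reads_only)
    W = params.window
    windows: list[PhaseWindow] = []
    for contig, occ in occupancy.items():
        clen = contig_lengths[contig]
        # per-position scores, computed once and reused across windows
        scores: dict[int, float] = {
            int(p): position_score(occ, int(p), params, clen).score
            for p in occ.unique_positions
        }
        for anchor in occ.unique_positions:
            anchor = int(anchor)
            if anchor + W - 1 > clen:
                continue
            n, k, P, U = window_counts(occ, anchor, anchor + W - 1, anchor, params.cycle)
            p_val = hypergeometric_pvalue(n, k, params)
            lo = np.searchsorted(occ.unique_positions, anchor, side="left")
            hi = np.searchsorted(occ.unique_positions, anchor + W - 1, side="right")
            in_reg = [
                int(p)
                for p in occ.unique_positions[lo:hi]
                if (int(p) - anchor) % params.cycle == 0
            ]
            max_score = max((scores[p] for p in in_reg), default=0.0)
            windows.append(
                PhaseWindow(
                    contig=contig, start=anchor, cycle=params.cycle, n=n, k=k,
                    p_value=p_val, max_phase_score=max_score, window=W,
                )
            )
    return windows


def windows_to_rows(windows: Sequence[PhaseWindow]) -> list[dict[str, object]]:
    """Flatten windows for TSV export."""
    return [
        {
            "contig": w.contig, "start": w.start, "end": w.end, "cycle": w.cycle,
            "n": w.n, "k": w.k, "p_value": w.p_value,
            "max_phase_score": w.max_phase_score,
        }
        for w in windows
    ]
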