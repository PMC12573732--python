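"""Marey-map rearrangement and recombination-suppression detection.

A Marey map plots genetic position (cM) against physical position (bp)
for the markers of one chromosome. On a collinear chromosome the plot
is monotone; a chromosome rearranged relative to the assembly shows
direction reversals and physical jumps. ``segment_marey`` cuts the
cM-ordered physical-position sequence into signed blocks and
``min_inversion_events`` counts the minimum number of inversions
(signed reversals; no translocation moves) needed to restore the
reference order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BlockArrangement",
    "segment_marey",
    "detect_suppression",
    "min_inversion_events",
]


@dataclass
class Block:
    block_id: int          # rank in physical (reference) order, 1-based
    sign: int              # +1 forward, -1 inverted
    cm_start: float
    cm_end: float
    bp_start: int
    bp_end: int
    n_markers: int


@dataclass
class BlockArrangement:
    """Signed blocks in cM order; ids form a permutation of 1..K."""

    blocks: list[Block]

    @property
    def signed(self) -> tuple[int, ...]:
        return tuple(b.sign * b.block_id for b in self.blocks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (b.block_id, b.sign, b.cm_start, b.cm_end, b.bp_start, b.bp_end,
                 b.n_markers)
                for b in self.blocks
            ],
            columns=["block", "sign", "cm_start", "cm_end", "bp_start", "bp_end",
                     "n_markers"],
        )


def _orientation(cm: np.ndarray, bp: np.ndarray) -> int:
    """Sign of the rank correlation between cM and bp within a block."""
    if len(bp) < 2:
        return 0
    rho = stats.spearmanr(cm, bp).statistic
    if not np.isfinite(rho) or rho == 0:
        return 0
    return 1 if rho > 0 else -1


def segment_marey(
    marey: pd.DataFrame,
    min_block_markers: int = 5,
    jump_threshold_mb: float = 2.0,
) -> BlockArrangement:
    """Segment a Marey map into signed rearrangement blocks.

    The cM-ordered bp sequence is split at direction changes and at
    physical jumps larger than ``jump_threshold_mb``; segments shorter
    than ``min_block_markers`` are merged into the physically closer
    neighbor, and adjacent segments that continue the same trend across
    a sub-threshold boundary are coalesced. Block ids are assigned by
    physical order in the reference; each block's sign is the sign of
    the within-block rank correlation between cM and bp (short
    ambiguous blocks inherit the neighboring orientation).
    """
    df = marey.sort_values("cM", kind="stable").reset_index(drop=True)
    if len(df) < 2 * min_block_markers:
        raise ValueError("need at least 2*min_block_markers markers")
    bp = df["bp"].to_numpy(dtype=float)
    cm = df["cM"].to_numpy(dtype=float)
    jump = jump_threshold_mb * 1e6
    d = np.diff(bp)
    cuts = [0]
    for i in range(1, len(bp)):
        if abs(d[i - 1]) > jump:
            cuts.append(i)
        elif (
            i >= 2
            and d[i - 1] != 0
            and d[i - 2] != 0
            and np.sign(d[i - 1]) != np.sign(d[i - 2])
            and cuts[-1] < i - 1
        ):
            cuts.append(i - 1)  # local extremum starts a new segment
    cuts = sorted(set(cuts))
    segments = [list(range(s, e)) for s, e in zip(cuts, cuts[1:] + [len(bp)]) if e > s]

    # merge short segments into the physically closer neighbor
    def bp_gap(a: list[int], b: list[int]) -> float:
        return abs(bp[b[0]] - bp[a[-1]])

    while len(segments) > 1:
        sizes = [len(s) for s in segments]
        if min(sizes) >= min_block_markers:
            break
        i = int(np.argmin(sizes))
        if i == 0:
            j = 1
        elif i == len(segments) - 1:
            j = i - 1
        else:
            j = i - 1 if bp_gap(segments[i - 1], segments[i]) <= bp_gap(
                segments[i], segments[i + 1]
            ) else i + 1
        a, b = sorted((i, j))
        segments[a] = segments[a] + segments[b]
        del segments[b]

    # coalesce neighbors that continue one trend: same orientation and
    # either a sub-threshold boundary gap or a gap crossing no other
    # segment's physical territory
    def can_merge(i: int) -> bool:
        a, b = segments[i], segments[i + 1]
        sa = _orientation(cm[a], bp[a])
        sb = _orientation(cm[b], bp[b])
        if sa != sb and sa != 0 and sb != 0:
            return False
        gap = bp[b[0]] - bp[a[-1]]
        if abs(gap) <= jump:
            return True
        trend = sa or sb
        if trend != 0 and np.sign(gap) != trend:
            return False
        lo, hi = sorted((bp[a[-1]], bp[b[0]]))
        for j, other in enumerate(segments):
            if j in (i, i + 1):
                continue
            if lo < np.median(bp[other]) < hi:
                return False  # another block owns the skipped territory
        return True

    changed = True
    while changed and len(segments) > 1:
        changed = False
        for i in range(len(segments) - 1):
            if can_merge(i):
                segments[i] = segments[i] + segments[i + 1]
                del segments[i + 1]
                changed = True
                break

    signs = [_orientation(cm[s], bp[s]) for s in segments]
    for i, s in enumerate(signs):
        if s == 0:  # short/tied block: inherit a neighbor's orientation
            left = signs[i - 1] if i > 0 else 0
            right = signs[i + 1] if i < len(signs) - 1 else 0
            signs[i] = left or right or 1
    mids = [np.median(bp[s]) for s in segments]
    phys_rank = {i: k + 1 for k, i in enumerate(np.argsort(mids, kind="stable"))}
    blocks = [
        Block(
            block_id=phys_rank[i],
            sign=signs[i],
            cm_start=float(cm[seg].min()),
            cm_end=float(cm[seg].max()),
            bp_start=int(bp[seg].min()),
            bp_end=int(bp[seg].max()),
            n_markers=len(seg),
        )
        for i, seg in enumerate(segments)
    ]
    return BlockArrangement(blocks=blocks)


def detect_suppression(
    marey: pd.DataFrame,
    min_span_mb: float = 2.0,
    min_markers: int = 3,
) -> pd.DataFrame:
    """Recombination-suppressed regions: runs of markers at one cM.

    Maximal runs of at least ``min_markers`` markers sharing a map
    position whose physical span reaches ``min_span_mb`` are reported
    with their cM position and bp interval.
    """
    df = marey.sort_values(["cM", "bp"], kind="stable").reset_index(drop=True)
    cm = df["cM"].to_numpy(dtype=float)
    bp = df["bp"].to_numpy(dtype=float)
    rows = []
    i = 0
    while i < len(cm):
        j = i
        while j + 1 < len(cm) and abs(cm[j + 1] - cm[i]) < 1e-9:
            j += 1
        if j - i + 1 >= min_markers:
            span = bp[i:j + 1].max() - bp[i:j + 1].min()
            if span >= min_span_mb * 1e6:
                rows.append(
                    (float(cm[i]), int(bp[i:j + 1].min()), int(bp[i:j + 1].max()),
                     j - i + 1, float(span / 1e6))
                )
        i = j + 1
    return pd.DataFrame(
        rows, columns=["cM", "bp_start", "bp_end", "n_markers", "span_mb"]
    )


def _reversals(state: tuple[int, ...]):
    k = len(state)
    for i in range(k):
        for j in range(i, k):
            seg = tuple(-x for x in reversed(state[i:j + 1]))
            yield state[:i] + seg + state[j + 1:]


def min_inversion_events(
    arrangement: BlockArrangement | tuple[int, ...] | list[int],
    max_blocks: int = 10,
) -> int:
    """Minimum signed reversals sorting the arrangement to +1..+K.

    Bidirectional breadth-first search over signed permutations;
    reversals only (no fission/fusion or translocation), matching an
    inversion-event count. Refuses arrangements above ``max_blocks``
    blocks — coarsen the segmentation instead.
    """
    signed = (
        arrangement.signed
        if isinstance(arrangement, BlockArrangement)
        else tuple(int(x) for x in arrangement)
    )
    k = len(signed)
    if k > max_blocks:
        raise ValueError(
            f"{k} blocks exceeds the exhaustive-search bound {max_blocks}; "
            "re-segment with a larger min_block_markers"
        )
    if sorted(abs(x) for x in signed) != list(range(1, k + 1)):
        raise ValueError("block ids must form a signed permutation of 1..K")
    target = tuple(range(1, k + 1))
    if signed == target:
        return 0

    def lower_bound(state: tuple[int, ...]) -> int:
        # signed breakpoints on the 0..k+1 extension; one reversal can
        # remove at most two, so ceil(b/2) is admissible
        ext = (0,) + state + (k + 1,)
        b = sum(1 for i in range(k + 1) if ext[i + 1] - ext[i] != 1)
        return (b + 1) // 2

    def dfs(state: tuple[int, ...], depth: int, budget: int) -> bool:
        if state == target:
            return True
        if depth + lower_bound(state) > budget:
            return False
        for nxt in _reversals(state):
            if dfs(nxt, depth + 1, budget):
                return True
        return False

    for budget in range(lower_bound(signed), k + 2):
        if dfs(signed, 0, budget):
            return budget
    raise RuntimeError("no reversal sorting found within the k+1 bound")
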