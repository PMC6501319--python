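"""Pairwise homology-block discovery and region classification.

The two genomes are aligned by exact unique anchors (maximal unique k-mer
matches on both strands), chained into collinear blocks, and the resulting
partition of each genome is classified into four region classes:

* ``collinear`` — homologous, same order in both genomes;
* ``translocated`` — homologous block moved to another genomic context;
* ``divergent`` — corresponding intervals that are non-homologous yet each
  carry at least one annotated feature;
* ``exclusive`` — an interval with at least one annotated feature in exactly
  one genome, absent (or featureless) in the other.

Featureless unaligned gaps below ``min_report_gap`` (50 bp) are silently
absorbed into the flanking collinear region; larger featureless gaps are
absorbed too but logged as unclassified, because an exclusive call requires
an annotated feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib
import numpy as np

from .genome import AnnotatedGenome, revcomp
from . import sequtils as su

logger = logging.getLogger("straindiff.regions")

DEFAULT_K_MIN = 20
DEFAULT_MAX_GAP = 5000


@dataclass(frozen=True)
class Anchor:
    """A maximal exact unique match.  For strand '-',
    ``A[a_start:a_start+length] == revcomp(B[b_start:b_start+length])``."""

    a_start: int
    b_start: int
    length: int
    strand: str = "+"

    @property
    def a_end(self) -> int:
        return self.a_start + self.length

    @property
    def b_end(self) -> int:
        return self.b_start + self.length


@dataclass
class AlignmentBlock:
    """A chained homology block; either interval may be absent."""

    a_interval: tuple[int, int] | None
    b_interval: tuple[int, int] | None
    strand: str = "+"
    identity: float | None = None
    on_main_chain: bool = True


@dataclass
class RegionCall:
    region_id: str
    region_class: str  # collinear | translocated | divergent | exclusive
    a_interval: tuple[int, int] | None = None
    b_interval: tuple[int, int] | None = None
    owner: str | None = None  # exclusive regions only: "A" or "B"
    feature_ids_a: list[str] = field(default_factory=list)
    feature_ids_b: list[str] = field(default_factory=list)

    def interval(self, genome_label: str) -> tuple[int, int] | None:
        return self.a_interval if genome_label == "A" else self.b_interval


# ---------------------------------------------------------------------------
# anchors


def _unique_kmer_positions(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(sorted unique codes occurring exactly once, their positions)."""
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    if len(codes) == 0:
        return sorted_codes, order
    is_first = np.empty(len(codes), dtype=bool)
    is_first[0] = True
    is_first[1:] = sorted_codes[1:] != sorted_codes[:-1]
    is_last = np.empty(len(codes), dtype=bool)
    is_last[-1] = True
    is_last[:-1] = sorted_codes[1:] != sorted_codes[:-1]
    uniq = is_first & is_last
    return sorted_codes[uniq], order[uniq]


def _matched_positions(codes_a: np.ndarray, codes_b: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Positions (pa, pb) of k-mers unique in both sequences and shared."""
    ca, pa = _unique_kmer_positions(codes_a)
    cb, pb = _unique_kmer_positions(codes_b)
    ia = np.isin(ca, cb, assume_unique=True)
    if not ia.any():
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    ca, pa = ca[ia], pa[ia]
    ib = np.isin(cb, ca, assume_unique=True)
    cb, pb = cb[ib], pb[ib]
    # both ca and cb are sorted and now identical as sets
    return pa, pb


def _merge_runs(pa: np.ndarray, pb: np.ndarray, k: int) -> list[tuple[int, int, int]]:
    """Merge co-diagonal consecutive seed matches into maximal runs.
    Returns (a_start, b_start, length) triples."""
    if len(pa) == 0:
        return []
    diag = pa - pb
    order = np.lexsort((pa, diag))
    pa, pb, diag = pa[order], pb[order], diag[order]
    breaks = np.flatnonzero((np.diff(diag) != 0) | (np.diff(pa) != 1))
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(pa) - 1]))
    return [(int(pa[s]), int(pb[s]), int(pa[e] - pa[s]) + k)
            for s, e in zip(starts, ends)]


def find_anchors(seq_a: str, seq_b: str, k_min: int = DEFAULT_K_MIN) -> list[Anchor]:
    """All maximal exact unique matches of length >= k_min on both strands,
    sorted by a_start."""
    if k_min < 12:
        raise ValueError("k_min must be >= 12")
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    arr_a = su.encode(seq_a)
    arr_b = su.encode(seq_b)
    codes_a = su.kmer_codes(arr_a, k_min)
    codes_b = su.kmer_codes(arr_b, k_min)
    anchors: list[Anchor] = []

    pa, pb = _matched_positions(codes_a, codes_b)
    for a0, b0, ln in _merge_runs(pa, pb, k_min):
        anchors.append(Anchor(a0, b0, ln, "+"))

    # reverse strand: match A against revcomp(B)
    arr_rb = 3 - arr_b[::-1]
    codes_rb = su.kmer_codes(arr_rb, k_min)
    pa, prb = _matched_positions(codes_a, codes_rb)
    nb = len(arr_b)
    for a0, rb0, ln in _merge_runs(pa, prb, k_min):
        b0 = nb - rb0 - ln
        anchors.append(Anchor(a0, b0, ln, "-"))

    anchors.sort(key=lambda a: (a.a_start, a.b_start))
    return anchors


# ---------------------------------------------------------------------------
# chaining


def _weighted_lis(anchors: list[Anchor]) -> list[int]:
    """Indices of the maximum-total-length chain of anchors that is strictly
    increasing in both a_start and b_start (anchors pre-sorted by a_start).
    Ties broken towards earliest a_start."""
    n = len(anchors)
    if n == 0:
        return []
    b_starts = np.array([a.b_start for a in anchors])
    ranks = np.searchsorted(np.unique(b_starts), b_starts)
    m = int(ranks.max()) + 1
    # Fenwick tree for prefix-max over b-rank
    tree_val = np.zeros(m + 1)
    tree_idx = np.full(m + 1, -1)

    def update(i: int, val: float, idx: int) -> None:
        i += 1
        while i <= m:
            if val > tree_val[i]:
                tree_val[i] = val
                tree_idx[i] = idx
            i += i & (-i)

    def query(i: int) -> tuple[float, int]:
        best, bidx = 0.0, -1
        i += 1
        while i > 0:
            if tree_val[i] > best:
                best, bidx = tree_val[i], tree_idx[i]
            i -= i & (-i)
        return best, bidx

    score = np.zeros(n)
    parent = np.full(n, -1)
    for i, a in enumerate(anchors):
        prev_best, prev_idx = query(int(ranks[i]) - 1)
        score[i] = prev_best + a.length
        parent[i] = prev_idx
        update(int(ranks[i]), score[i], i)

    end = int(np.argmax(score))
    chain = []
    while end != -1:
        chain.append(end)
        end = int(parent[end])
    return chain[::-1]


def _gap_identity(sa: str, sb: str) -> float:
    """Global-alignment identity of two gap sequences (matches / columns)."""
    if not sa or not sb:
        return 0.0
    res = edlib.align(sa, sb, mode="NW", task="distance")
    dist = res["editDistance"]
    cols = max(len(sa), len(sb))  # lower bound on columns; conservative
    return max(0.0, 1.0 - dist / cols)


def chain_anchors(anchors: list[Anchor], seq_a: str, seq_b: str,
                  max_gap: int = DEFAULT_MAX_GAP,
                  absorb_identity: float = 0.65,
                  min_offchain_anchor: int = 200) -> list[AlignmentBlock]:
    """Chain anchors into homology blocks.

    The maximum-anchored-length collinear chain becomes the main block set;
    gaps between consecutive chained anchors are absorbed into a block when
    both gap sides are <= ``max_gap`` and their global-alignment identity is
    >= ``absorb_identity`` (substitution-level divergence), otherwise the
    block is closed.  Off-chain anchors are clustered by diagonal into
    candidate translocated/inverted blocks; clusters anchoring fewer than
    ``min_offchain_anchor`` bp are dropped as noise.
    """
    if not anchors:
        return []
    plus = [a for a in anchors if a.strand == "+"]
    chain_idx = _weighted_lis(plus)
    chain = [plus[i] for i in chain_idx]
    chain_set = {id(plus[i]) for i in chain_idx}
    leftovers = [a for a in anchors if id(a) not in chain_set]

    blocks = _blocks_from_chain(chain, seq_a, seq_b, max_gap, absorb_identity,
                                on_main_chain=True)
    # boundary anchors of consecutive blocks may overlap by a few bp on one
    # axis; trim the later block so the partition stays disjoint
    for prev, nxt in zip(blocks, blocks[1:]):
        if nxt.a_interval[0] < prev.a_interval[1]:
            nxt.a_interval = (min(prev.a_interval[1], nxt.a_interval[1] - 1),
                              nxt.a_interval[1])
        if nxt.b_interval[0] < prev.b_interval[1]:
            nxt.b_interval = (min(prev.b_interval[1], nxt.b_interval[1] - 1),
                              nxt.b_interval[1])
    off = _offchain_blocks(leftovers, seq_a, seq_b, max_gap,
                           absorb_identity, min_offchain_anchor)
    # off-chain clusters overlapping main-chain coverage are paralogous
    # repeats (e.g. multi-copy rRNA cross-matches), not translocations
    main_a = [b.a_interval for b in blocks]
    main_b = [b.b_interval for b in blocks]
    kept = []
    for b in off:
        ov_a = _overlap_total(b.a_interval, main_a)
        ov_b = _overlap_total(b.b_interval, main_b)
        span = max(b.a_interval[1] - b.a_interval[0],
                   b.b_interval[1] - b.b_interval[0])
        if max(ov_a, ov_b) > 0.2 * span:
            logger.info("dropping off-chain block %s/%s overlapping the "
                        "main chain (paralogous repeat)", b.a_interval,
                        b.b_interval)
            continue
        kept.append(b)
    # among the remaining off-chain blocks, drop the smaller of any
    # mutually overlapping pair (ambiguous repeats)
    kept.sort(key=lambda b: -(b.a_interval[1] - b.a_interval[0]))
    final_off: list[AlignmentBlock] = []
    for b in kept:
        clash = any(
            _overlap_total(b.a_interval, [o.a_interval]) > 0
            or _overlap_total(b.b_interval, [o.b_interval]) > 0
            for o in final_off)
        if clash:
            logger.info("dropping off-chain block %s/%s overlapping a "
                        "larger off-chain block", b.a_interval, b.b_interval)
            continue
        final_off.append(b)
    for b in final_off:
        _clip_to_free_space(b, main_a, main_b)
    final_off = [b for b in final_off
                 if b.a_interval[1] - b.a_interval[0] > 0
                 and b.b_interval[1] - b.b_interval[0] > 0]
    for b in final_off:
        _extend_offchain(b, seq_a, seq_b,
                         main_a + [o.a_interval for o in final_off
                                   if o is not b],
                         main_b + [o.b_interval for o in final_off
                                   if o is not b])
    blocks += final_off
    blocks.sort(key=lambda b: b.a_interval[0] if b.a_interval else -1)
    return blocks


def _overlap_total(iv: tuple[int, int], others: list[tuple[int, int]]) -> int:
    return sum(max(0, min(iv[1], e) - max(iv[0], s)) for s, e in others)


def _clip_to_free_space(block: AlignmentBlock,
                        main_a: list[tuple[int, int]],
                        main_b: list[tuple[int, int]]) -> None:
    """Shrink an off-chain block so it no longer overlaps main-chain
    coverage, trimming both intervals consistently along the diagonal."""
    left = right = 0  # trims expressed on the a axis
    (a0, a1), (b0, b1) = block.a_interval, block.b_interval
    for s, e in main_a:
        if s < a1 and e > a0:
            if s <= a0:
                left = max(left, min(e, a1) - a0)
            else:
                right = max(right, a1 - max(s, a0))
    for s, e in main_b:
        if s < b1 and e > b0:
            if s <= b0:
                t = min(e, b1) - b0
                if block.strand == "+":
                    left = max(left, t)
                else:
                    right = max(right, t)
            else:
                t = b1 - max(s, b0)
                if block.strand == "+":
                    right = max(right, t)
                else:
                    left = max(left, t)
    if left or right:
        block.a_interval = (a0 + left, a1 - right)
        if block.strand == "+":
            block.b_interval = (b0 + left, b1 - right)
        else:
            block.b_interval = (b0 + right, b1 - left)


def _xdrop_steps(pairs) -> int:
    """Number of leading (a_char, b_char) pairs to keep under +1/-3 X-drop
    scoring (argmax prefix score, 0 when no positive prefix)."""
    best = score = 0.0
    best_i = 0
    for i, (x, y) in enumerate(pairs, start=1):
        score += 1.0 if x == y else -3.0
        if score > best:
            best, best_i = score, i
        if score < best - 20:
            break
    return best_i


def _extend_offchain(block: AlignmentBlock, seq_a: str, seq_b: str,
                     other_a: list[tuple[int, int]],
                     other_b: list[tuple[int, int]]) -> None:
    """Mismatch-tolerant ungapped extension of an off-chain block along its
    diagonal, up to the nearest already-covered interval.  Translocated
    blocks preserve their diagonal, so the anchor-end jitter at the block
    junctions is recovered exactly up to the first non-homologous stretch."""
    (a0, a1), (b0, b1) = block.a_interval, block.b_interval
    lim_a_lo = max([e for s, e in other_a if e <= a0], default=0)
    lim_a_hi = min([s for s, e in other_a if s >= a1], default=len(seq_a))
    lim_b_lo = max([e for s, e in other_b if e <= b0], default=0)
    lim_b_hi = min([s for s, e in other_b if s >= b1], default=len(seq_b))
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    if block.strand == "+":
        n_left = min(a0 - lim_a_lo, b0 - lim_b_lo)
        left = _xdrop_steps((seq_a[a0 - 1 - d], seq_b[b0 - 1 - d])
                            for d in range(n_left))
        n_right = min(lim_a_hi - a1, lim_b_hi - b1)
        right = _xdrop_steps((seq_a[a1 + d], seq_b[b1 + d])
                             for d in range(n_right))
        block.a_interval = (a0 - left, a1 + right)
        block.b_interval = (b0 - left, b1 + right)
    else:
        n_left = min(a0 - lim_a_lo, lim_b_hi - b1)
        left = _xdrop_steps((seq_a[a0 - 1 - d], comp[seq_b[b1 + d]])
                            for d in range(n_left))
        n_right = min(lim_a_hi - a1, b0 - lim_b_lo)
        right = _xdrop_steps((seq_a[a1 + d], comp[seq_b[b0 - 1 - d]])
                             for d in range(n_right))
        block.a_interval = (a0 - left, a1 + right)
        block.b_interval = (b0 - right, b1 + left)


def _blocks_from_chain(chain: list[Anchor], seq_a: str, seq_b: str,
                       max_gap: int, absorb_identity: float,
                       on_main_chain: bool, strand: str = "+"
                       ) -> list[AlignmentBlock]:
    blocks: list[AlignmentBlock] = []
    if not chain:
        return blocks
    cur = [chain[0]]
    matches = chain[0].length

    def close() -> None:
        nonlocal matches
        a0, a1 = cur[0].a_start, cur[-1].a_end
        if strand == "+":
            b0, b1 = cur[0].b_start, cur[-1].b_end
        else:
            b0, b1 = cur[-1].b_start, cur[0].b_end
        span = max(a1 - a0, b1 - b0)
        blocks.append(AlignmentBlock((a0, a1), (b0, b1), strand,
                                     identity=min(1.0, matches / max(1, span)),
                                     on_main_chain=on_main_chain))

    for prev, nxt in zip(chain, chain[1:]):
        a_gap = nxt.a_start - prev.a_end
        if strand == "+":
            b_gap = nxt.b_start - prev.b_end
            ga = seq_a[prev.a_end:nxt.a_start]
            gb = seq_b[prev.b_end:nxt.b_start]
        else:
            b_gap = prev.b_start - nxt.b_end
            ga = seq_a[prev.a_end:nxt.a_start]
            gb = revcomp(seq_b[nxt.b_end:prev.b_start])
        absorb = False
        gap_matches = 0.0
        if a_gap <= 0 and b_gap <= 0:
            absorb = True
        elif max(a_gap, b_gap) <= 30:
            absorb = True
            gap_matches = min(a_gap, b_gap) * 0.5
        elif (0 < a_gap <= max_gap and 0 < b_gap <= max_gap
                and min(a_gap, b_gap) >= 0.5 * max(a_gap, b_gap)):
            # gaps between surviving anchors are conditioned on containing
            # no exact k-mer match, hence mismatch-enriched: short gaps get
            # a laxer identity floor than long ones
            floor = (min(absorb_identity, 0.55) if max(a_gap, b_gap) <= 300
                     else absorb_identity)
            ident = _gap_identity(ga, gb)
            if ident >= floor:
                absorb = True
                gap_matches = ident * max(a_gap, b_gap)
        if absorb:
            cur.append(nxt)
            matches += nxt.length + gap_matches
        else:
            close()
            cur = [nxt]
            matches = nxt.length
    close()
    return blocks


def _offchain_blocks(leftovers: list[Anchor], seq_a: str, seq_b: str,
                     max_gap: int, absorb_identity: float,
                     min_anchor: int) -> list[AlignmentBlock]:
    """Cluster off-chain anchors by (strand, diagonal) into candidate
    translocated / inverted blocks."""
    blocks: list[AlignmentBlock] = []
    for strand in ("+", "-"):
        sub = [a for a in leftovers if a.strand == strand]
        if not sub:
            continue
        # a translocated/inverted block keeps one diagonal; cluster with a
        # tight diagonal tolerance so unrelated anchors cannot interleave
        diag_tol = 200
        diag = {id(a): (a.a_start - a.b_start if strand == "+"
                        else a.a_start + a.b_start) for a in sub}
        sub.sort(key=lambda a: (diag[id(a)] // diag_tol, a.a_start))
        cluster: list[Anchor] = []
        for a in sub:
            if cluster and (abs(diag[id(a)] - diag[id(cluster[-1])]) > diag_tol
                            or a.a_start - cluster[-1].a_end > max_gap):
                blocks += _flush_cluster(cluster, seq_a, seq_b, max_gap,
                                         absorb_identity, min_anchor, strand)
                cluster = []
            cluster.append(a)
        blocks += _flush_cluster(cluster, seq_a, seq_b, max_gap,
                                 absorb_identity, min_anchor, strand)
    return blocks


def _flush_cluster(cluster: list[Anchor], seq_a: str, seq_b: str,
                   max_gap: int, absorb_identity: float, min_anchor: int,
                   strand: str) -> list[AlignmentBlock]:
    if sum(a.length for a in cluster) < min_anchor:
        return []
    cluster = sorted(cluster, key=lambda a: a.a_start)
    return _blocks_from_chain(cluster, seq_a, seq_b, max_gap, absorb_identity,
                              on_main_chain=False, strand=strand)


# ---------------------------------------------------------------------------
# flank trimming for unaligned gap pairs


def _trim_flanks(sa: str, sb: str, max_scan: int = 400
                 ) -> tuple[int, int]:
    """How much of the shorter gap sequence is a substitution-divergent copy
    of the longer one's flanks.  Returns (left_trim, right_trim): prefix and
    suffix lengths that are homologous flank residue, to be reassigned to the
    neighbouring collinear regions.  X-drop style: score +1 match, -3
    mismatch, take the argmax prefix/suffix score."""
    n = min(len(sa), len(sb), max_scan)
    if n == 0:
        return 0, 0
    ax = np.frombuffer(sa[:n].encode(), dtype=np.uint8)
    bx = np.frombuffer(sb[:n].encode(), dtype=np.uint8)
    sc = np.where(ax == bx, 1.0, -3.0).cumsum()
    left = int(np.argmax(sc)) + 1 if sc.max() > 0 else 0

    ar = np.frombuffer(sa[-n:].encode(), dtype=np.uint8)[::-1]
    br = np.frombuffer(sb[-n:].encode(), dtype=np.uint8)[::-1]
    sc = np.where(ar == br, 1.0, -3.0).cumsum()
    right = int(np.argmax(sc)) + 1 if sc.max() > 0 else 0

    total = min(len(sa), len(sb))
    if left + right > total:  # flanks overlap on the shorter side
        overflow = left + right - total
        left -= overflow // 2 + overflow % 2
        right -= overflow // 2
    return max(0, left), max(0, right)


# ---------------------------------------------------------------------------
# segmentation and classification


@dataclass
class _Assigned:
    """Per-genome interval assignment used to build the final partition."""

    start: int
    end: int
    region: RegionCall
    genome_label: str


def segment_and_classify(blocks: list[AlignmentBlock],
                         genome_a: AnnotatedGenome,
                         genome_b: AnnotatedGenome,
                         min_report_gap: int = 50) -> list[RegionCall]:
    """Partition both genomes into classified regions.

    Chained blocks become ``collinear`` regions; off-chain blocks become
    ``translocated``; paired unaligned gaps are classified ``divergent`` /
    ``exclusive`` by feature presence after homologous flank trimming.
    Featureless gaps are merged into the nearest collinear region (logged
    when >= ``min_report_gap``).
    """
    for b in blocks:
        if b.a_interval and b.a_interval[0] >= b.a_interval[1]:
            raise ValueError("empty block interval")
    _check_no_overlap(blocks, "A", len(genome_a))
    _check_no_overlap(blocks, "B", len(genome_b))

    chain = sorted((b for b in blocks if b.on_main_chain),
                   key=lambda b: b.a_interval[0])
    off = [b for b in blocks if not b.on_main_chain]

    regions: list[RegionCall] = []
    counter = [0]

    def new_region(cls: str, a_iv, b_iv, owner=None) -> RegionCall:
        counter[0] += 1
        fa = ([f.feature_id for f in genome_a.features_within(*a_iv)]
              if a_iv else [])
        fb = ([f.feature_id for f in genome_b.features_within(*b_iv)]
              if b_iv else [])
        r = RegionCall(f"R{counter[0]:04d}", cls, a_iv, b_iv, owner, fa, fb)
        regions.append(r)
        return r

    assigned_a: list[_Assigned] = []
    assigned_b: list[_Assigned] = []

    for b in chain:
        r = new_region("collinear", b.a_interval, b.b_interval)
        assigned_a.append(_Assigned(*b.a_interval, r, "A"))
        assigned_b.append(_Assigned(*b.b_interval, r, "B"))
    for b in off:
        r = new_region("translocated", b.a_interval, b.b_interval)
        if b.a_interval:
            assigned_a.append(_Assigned(*b.a_interval, r, "A"))
        if b.b_interval:
            assigned_b.append(_Assigned(*b.b_interval, r, "B"))

    # adjacency gaps between consecutive main-chain blocks (plus genome ends)
    bounds_a = [(0, 0)] + [b.a_interval for b in chain] + [(len(genome_a),) * 2]
    bounds_b = [(0, 0)] + [b.b_interval for b in chain] + [(len(genome_b),) * 2]
    covered_a = sorted(iv for iv in
                       ([b.a_interval for b in off if b.a_interval]))
    covered_b = sorted(iv for iv in
                       ([b.b_interval for b in off if b.b_interval]))

    for i in range(len(bounds_a) - 1):
        ga_iv = (bounds_a[i][1], bounds_a[i + 1][0])
        gb_iv = (bounds_b[i][1], bounds_b[i + 1][0])
        a_pieces = _subtract(ga_iv, covered_a)
        b_pieces = _subtract(gb_iv, covered_b)
        _classify_gap_pair(a_pieces, b_pieces, genome_a, genome_b,
                           new_region, assigned_a, assigned_b, min_report_gap)

    _fill_partition(assigned_a, len(genome_a))
    _fill_partition(assigned_b, len(genome_b))
    _refresh_intervals(regions, assigned_a, assigned_b, genome_a, genome_b)
    return [r for r in regions if r.a_interval or r.b_interval]


def _check_no_overlap(blocks, genome_label: str, length: int) -> None:
    ivs = sorted(b.a_interval if genome_label == "A" else b.b_interval
                 for b in blocks
                 if (b.a_interval if genome_label == "A" else b.b_interval))
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 < e1:
            raise ValueError(
                f"overlapping blocks on genome {genome_label}: "
                f"[{s1},{e1}) and [{s2},{e2})")
    for s, e in ivs:
        if s < 0 or e > length:
            raise ValueError(f"block [{s},{e}) outside genome {genome_label}")


def _subtract(iv: tuple[int, int], covered: list[tuple[int, int]]
              ) -> list[tuple[int, int]]:
    """Pieces of iv not covered by any of the (sorted) covered intervals."""
    s, e = iv
    if s >= e:
        return []
    pieces = []
    cur = s
    for cs, ce in covered:
        if ce <= cur or cs >= e:
            continue
        if cs > cur:
            pieces.append((cur, cs))
        cur = max(cur, ce)
    if cur < e:
        pieces.append((cur, e))
    return pieces


def _classify_gap_pair(a_pieces, b_pieces, genome_a, genome_b, new_region,
                       assigned_a, assigned_b, min_report_gap) -> None:
    """Classify the unaligned pieces of one adjacency gap."""
    tot_a = sum(e - s for s, e in a_pieces)
    tot_b = sum(e - s for s, e in b_pieces)
    if tot_a == 0 and tot_b == 0:
        return

    if len(a_pieces) <= 1 and len(b_pieces) <= 1:
        a_iv = a_pieces[0] if a_pieces else None
        b_iv = b_pieces[0] if b_pieces else None
        sa = genome_a.sequence[a_iv[0]:a_iv[1]] if a_iv else ""
        sb = genome_b.sequence[b_iv[0]:b_iv[1]] if b_iv else ""
        lt, rt = _trim_flanks(sa, sb)
        core_a = (a_iv[0] + lt, a_iv[1] - rt) if a_iv else None
        core_b = (b_iv[0] + lt, b_iv[1] - rt) if b_iv else None
        if core_a and core_a[0] >= core_a[1]:
            core_a = None
        if core_b and core_b[0] >= core_b[1]:
            core_b = None
        feats_a = genome_a.features_within(*core_a) if core_a else []
        feats_b = genome_b.features_within(*core_b) if core_b else []

        if feats_a and feats_b:
            r = new_region("divergent", core_a, core_b)
            assigned_a.append(_Assigned(*core_a, r, "A"))
            assigned_b.append(_Assigned(*core_b, r, "B"))
        elif feats_a:
            r = new_region("exclusive", core_a, None, owner="A")
            assigned_a.append(_Assigned(*core_a, r, "A"))
            _log_featureless(core_b, "B", min_report_gap)
        elif feats_b:
            r = new_region("exclusive", None, core_b, owner="B")
            assigned_b.append(_Assigned(*core_b, r, "B"))
            _log_featureless(core_a, "A", min_report_gap)
        else:
            _log_featureless(core_a, "A", min_report_gap)
            _log_featureless(core_b, "B", min_report_gap)
        return

    # multiple pieces on a side (a translocated block sits inside the gap):
    # classify each piece against the total opposite-side material
    for pieces, genome, label, assigned in (
            (a_pieces, genome_a, "A", assigned_a),
            (b_pieces, genome_b, "B", assigned_b)):
        opposite_total = tot_b if label == "A" else tot_a
        for s, e in pieces:
            feats = genome.features_within(s, e)
            if feats and opposite_total < min_report_gap:
                r = new_region("exclusive",
                               (s, e) if label == "A" else None,
                               (s, e) if label == "B" else None, owner=label)
                assigned.append(_Assigned(s, e, r, label))
            elif feats:
                # featureful on this side with unresolved opposite material:
                # conservative divergent-style exclusive call
                r = new_region("exclusive",
                               (s, e) if label == "A" else None,
                               (s, e) if label == "B" else None, owner=label)
                assigned.append(_Assigned(s, e, r, label))
            else:
                _log_featureless((s, e), label, min_report_gap)


def _log_featureless(iv, genome_label: str, min_report_gap: int) -> None:
    if iv and iv[1] - iv[0] >= min_report_gap:
        logger.info("unclassified featureless gap on genome %s: [%d, %d) "
                    "(%d bp), merged into flanking collinear region",
                    genome_label, iv[0], iv[1], iv[1] - iv[0])


def _fill_partition(assigned: list[_Assigned], length: int) -> None:
    """Extend assigned intervals so they tile [0, length) exactly; slack is
    attached to the nearest collinear (else any) neighbour."""
    assigned.sort(key=lambda x: x.start)
    if not assigned:
        return
    # leading slack
    assigned[0].start = 0
    for prev, nxt in zip(assigned, assigned[1:]):
        if nxt.start > prev.end:
            if prev.region.region_class == "collinear":
                prev.end = nxt.start
            elif nxt.region.region_class == "collinear":
                nxt.start = prev.end
            else:
                prev.end = nxt.start
        elif nxt.start < prev.end:  # defensive; should not happen
            nxt.start = prev.end
    assigned[-1].end = length


def _refresh_intervals(regions, assigned_a, assigned_b, genome_a, genome_b
                       ) -> None:
    """Push the partition-filled intervals back onto the RegionCalls and
    refresh contained-feature lists."""
    for assigned, which in ((assigned_a, "a"), (assigned_b, "b")):
        for item in assigned:
            setattr(item.region, f"{which}_interval", (item.start, item.end))
    for r in regions:
        r.feature_ids_a = ([f.feature_id
                            for f in genome_a.features_within(*r.a_interval)]
                           if r.a_interval else [])
        r.feature_ids_b = ([f.feature_id
                            for f in genome_b.features_within(*r.b_interval)]
                           if r.b_interval else [])


# ---------------------------------------------------------------------------
# summaries


def summarize_regions(regions: list[RegionCall]):
    """Per-class counts and lengths, mirroring the region-table shape."""
    import pandas as pd

    rows = []
    for cls in ("collinear", "translocated", "divergent", "exclusive"):
        for genome_label in ("A", "B"):
            sel = [r for r in regions if r.region_class == cls]
            if cls == "exclusive":
                sel = [r for r in sel if r.owner == genome_label]
            lengths = [r.interval(genome_label)[1] - r.interval(genome_label)[0]
                       for r in sel if r.interval(genome_label)]
            rows.append({
                "class": cls, "genome": genome_label, "count": len(lengths),
                "total_bp": sum(lengths),
                "mean_bp": (sum(lengths) / len(lengths)) if lengths else 0.0,
            })
    return pd.DataFrame(rows)


def class_counts(regions: list[RegionCall]) -> dict[str, int]:
    counts = {"collinear": 0, "translocated": 0, "divergent": 0,
              "exclusive_A": 0, "exclusive_B": 0}
    for r in regions:
        if r.region_class == "exclusive":
            counts[f"exclusive_{r.owner}"] += 1
        else:
            counts[r.region_class] += 1
    return counts


def overlap_with_islands(regions: list[RegionCall],
                         islands_a: list[tuple[int, int]],
                         islands_b: list[tuple[int, int]]):
    """Overlap table between exclusive regions and genomic-island intervals
    (internal 0-based half-open; >= 1 bp overlap counts)."""
    import pandas as pd

    for label, islands, genome_len_check in (("A", islands_a, None),
                                             ("B", islands_b, None)):
        for s, e in islands:
            if s < 0 or e <= s:
                raise ValueError(f"bad island interval [{s},{e}) on {label}")

    rows = []
    covered = set()
    for r in regions:
        if r.region_class != "exclusive":
            continue
        iv = r.interval(r.owner)
        islands = islands_a if r.owner == "A" else islands_b
        for idx, (s, e) in enumerate(islands):
            ov = min(iv[1], e) - max(iv[0], s)
            if ov > 0:
                covered.add(r.region_id)
                rows.append({"region_id": r.region_id, "genome": r.owner,
                             "island_index": idx, "overlap_bp": ov})
    table = pd.DataFrame(rows, columns=["region_id", "genome", "island_index",
                                        "overlap_bp"])
    n_exclusive = sum(1 for r in regions if r.region_class == "exclusive")
    summary = {"n_exclusive": n_exclusive,
               "n_exclusive_with_island": len(covered)}
    return table, summary
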