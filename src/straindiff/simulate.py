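"""Synthetic annotated genome pairs with a known evolutionary event log.

The generator emulates the statistical structure of a pair of closely related
bacterial strains: a common ancestor carrying protein-coding genes (and a few
near-identical rRNA-like multi-copy genes), evolved into two derived genomes
by independent substitutions plus structural events — gene-bearing island
insertions (with transposase/integrase marker genes), deletions, divergent
replacements and a translocation.  Every applied event is recorded in a
:class:`TruthLog` in final coordinates, which downstream classifiers are
tested against.

Substitution semantics: ``substitution_rate`` is the *pairwise* divergence
between the two derived genomes (the aligned-site mismatch fraction), not the
per-lineage rate.  Each lineage is mutated at the per-site rate ``q`` solving
``2q - (4/3)q^2 = rate`` so that the expected mismatch fraction equals the
requested rate.  Substitutions inside CDS are applied codon-wise and any
substitution creating a premature stop codon is resampled, so ORFs stay
intact and protein orthology remains testable.  Start and terminal stop
codons are left unmutated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .genome import AnnotatedGenome, Feature, revcomp
from . import sequtils as su

STOP_CODES = {
    (3, 0, 0),  # TAA
    (3, 0, 2),  # TAG
    (3, 2, 0),  # TGA
}

TRANSPOSASE_KO = "K07483"
TRANSPOSASE_COG = "COG2801"


@dataclass(frozen=True)
class AncestorSpec:
    """Parameters of the simulated common-ancestor genome."""

    genome_length: int = 200_000
    gene_count: int = 180
    gene_length_mean: int = 900
    gene_length_sd: int = 200
    gc_fraction: float = 0.44
    rng_seed: int = 0
    intergenic_min: int = 30
    n_rrna: int = 3
    rrna_length: int = 1200

    def validate(self) -> None:
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must lie in (0, 1)")
        if self.gene_count < 0 or self.genome_length <= 0:
            raise ValueError("gene_count and genome_length must be non-negative")


@dataclass(frozen=True)
class EventSpec:
    """Structural and substitutional events applied to the ancestor.

    ``substitution_rate`` is the target pairwise divergence; see module
    docstring.  Island lengths are drawn uniformly from
    ``island_length_range``; each island gene is tagged as a
    transposase/integrase mobility marker with probability
    ``mobility_marker_prob``.
    """

    substitution_rate: float = 0.12
    n_insertions: int = 5
    n_deletions: int = 3
    n_divergent: int = 2
    n_translocations: int = 1
    island_length_range: tuple[int, int] = (3000, 8000)
    mobility_marker_prob: float = 0.5
    rng_seed: int = 0
    deletion_genes: tuple[int, int] = (1, 3)
    translocation_length: int = 12_000
    translocation_offset: int = 50_000
    min_event_spacing: int = 4000
    island_gc_offset: float = 0.06

    def validate(self) -> None:
        if not 0 <= self.substitution_rate < 1:
            raise ValueError("substitution_rate must lie in [0, 1)")
        for n in (self.n_insertions, self.n_deletions, self.n_divergent,
                  self.n_translocations):
            if n < 0:
                raise ValueError("event counts must be >= 0")
        lo, hi = self.island_length_range
        if lo > hi:
            raise ValueError("island_length_range min must be <= max")


@dataclass
class TruthEvent:
    """One applied event, in final coordinates of each derived genome.

    Intervals are 0-based half-open; ``None`` means the event leaves no
    homologous counterpart interval in that genome (e.g. an insertion into A
    has ``b_interval is None``).
    """

    event_type: str  # substitution_bulk | insertion | deletion | divergent_replacement | translocation
    genome: str  # "A" or "B": the genome the edit was applied to
    a_interval: tuple[int, int] | None = None
    b_interval: tuple[int, int] | None = None
    payload_ids: list[str] = field(default_factory=list)

    def expected_region_class(self) -> str | None:
        """Region class the alignment classifier should call for this event."""
        return {
            "insertion": "exclusive",
            "deletion": "exclusive",
            "divergent_replacement": "divergent",
            "translocation": "translocated",
        }.get(self.event_type)

    def expected_owner(self) -> str | None:
        """Owner genome of the expected exclusive region, if any."""
        if self.event_type == "insertion":
            return self.genome
        if self.event_type == "deletion":
            return "B" if self.genome == "A" else "A"
        return None


@dataclass
class TruthLog:
    events: list[TruthEvent] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    def structural(self) -> list[TruthEvent]:
        return [e for e in self.events if e.event_type != "substitution_bulk"]

    def of_type(self, event_type: str) -> list[TruthEvent]:
        return [e for e in self.events if e.event_type == event_type]

    def expected_region_counts(self) -> dict[str, int]:
        """Per-class region counts implied by the structural events."""
        counts = {"exclusive_A": 0, "exclusive_B": 0, "divergent": 0,
                  "translocated": 0}
        for e in self.structural():
            cls = e.expected_region_class()
            if cls == "exclusive":
                counts[f"exclusive_{e.expected_owner()}"] += 1
            elif cls is not None:
                counts[cls] += 1
        return counts


def per_lineage_rate(pairwise_rate: float) -> float:
    """Per-lineage substitution probability giving the requested pairwise
    mismatch fraction (uniform substitution among the 3 other bases)."""
    if pairwise_rate == 0:
        return 0.0
    # mismatch = 2q(1-q) + q^2 * 2/3  =>  2q - (4/3) q^2 = r
    return (2 - math.sqrt(4 - (16 / 3) * pairwise_rate)) / (8 / 3)


# ---------------------------------------------------------------------------
# ancestor generation


def _gene_arrays(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    """An ORF as base-index array: ATG + sense codons + stop."""
    if length % 3 or length < 9:
        raise ValueError("gene length must be a multiple of 3 and >= 9")
    arr = su.random_sequence(length, gc, rng)
    arr[0:3] = [0, 3, 2]  # ATG
    arr[-3:] = [3, 0, 0]  # TAA
    _repair_internal_stops(arr, rng)
    return arr


def _repair_internal_stops(arr: np.ndarray, rng: np.random.Generator) -> None:
    """Destroy internal stop codons in-place by swapping one of their bases
    with another base of the gene body.  Swaps are permutations, so the
    letter composition of the gene (hence the genome-wide GC fraction) is
    exactly preserved."""
    n_codons = len(arr) // 3

    def codon(c: int) -> tuple[int, int, int]:
        return (int(arr[3 * c]), int(arr[3 * c + 1]), int(arr[3 * c + 2]))

    while True:
        stops = [c for c in range(1, n_codons - 1) if codon(c) in STOP_CODES]
        if not stops:
            return
        for c in stops:
            for _ in range(200):
                i = 3 * c + int(rng.integers(0, 3))
                j = int(rng.integers(3, len(arr) - 3))  # spare start/stop
                if arr[i] == arr[j]:
                    continue
                arr[i], arr[j] = arr[j], arr[i]
                ci, cj = i // 3, j // 3
                if any(1 <= cc <= n_codons - 2 and codon(cc) in STOP_CODES
                       for cc in {ci, cj}):
                    arr[i], arr[j] = arr[j], arr[i]  # revert
                    continue
                break


def generate_ancestor(spec: AncestorSpec) -> AnnotatedGenome:
    """Generate a circular ancestor genome (emitted linearised from position
    1) with non-overlapping CDS on both strands and ``n_rrna`` near-identical
    rRNA-like multi-copy genes.

    Raises ``ValueError`` if the requested genes cannot be packed into
    ``genome_length`` with the minimum intergenic spacing.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)

    gene_lengths = []
    for _ in range(spec.gene_count):
        ln = int(rng.normal(spec.gene_length_mean, spec.gene_length_sd))
        ln = max(150, ln)
        ln -= ln % 3
        gene_lengths.append(ln)

    units: list[tuple[str, int]] = [("CDS", ln) for ln in gene_lengths]
    units += [("rRNA", spec.rrna_length)] * (spec.n_rrna if spec.gene_count else 0)
    rng.shuffle(units)

    total_feat = sum(ln for _, ln in units)
    min_needed = total_feat + spec.intergenic_min * (len(units) + 1)
    if min_needed > spec.genome_length:
        raise ValueError(
            f"cannot pack {len(units)} features totalling {total_feat} bp plus "
            f"{spec.intergenic_min} bp minimum intergenic spacing into "
            f"{spec.genome_length} bp (needs >= {min_needed})"
        )

    slack = spec.genome_length - min_needed
    n_gaps = len(units) + 1
    extra = rng.multinomial(slack, np.ones(n_gaps) / n_gaps) if n_gaps else []
    seq = su.random_sequence(spec.genome_length, spec.gc_fraction, rng)

    rrna_template = su.random_sequence(spec.rrna_length, spec.gc_fraction, rng)
    features: list[Feature] = []
    pos = 0
    n_cds = 0
    n_rrna = 0
    for i, (kind, ln) in enumerate(units):
        pos += spec.intergenic_min + int(extra[i])
        if kind == "CDS":
            n_cds += 1
            strand = "+" if rng.random() < 0.5 else "-"
            oriented = _gene_arrays(ln, spec.gc_fraction, rng)
            placed = oriented if strand == "+" else 3 - oriented[::-1]
            seq[pos : pos + ln] = placed
            prot = su.translate(su.decode(oriented))
            features.append(Feature(
                feature_id=f"anc_{n_cds:05d}", kind="CDS", start=pos,
                end=pos + ln, strand=strand,
                product=f"hypothetical protein {n_cds}", protein=prot,
            ))
        else:
            n_rrna += 1
            copy = rrna_template.copy()
            for _ in range(int(rng.integers(0, 3))):  # near-identical copies
                p = int(rng.integers(0, len(copy)))
                copy[p] = (copy[p] + rng.integers(1, 4)) % 4
            seq[pos : pos + ln] = copy
            features.append(Feature(
                feature_id=f"anc_rrna_{n_rrna}", kind="rRNA", start=pos,
                end=pos + ln, strand="+", product="16S-like ribosomal RNA",
            ))
        pos += ln

    return AnnotatedGenome("ancestor", su.decode(seq), features)


# ---------------------------------------------------------------------------
# substitutions


def _mutate_lineage(genome: AnnotatedGenome, q: float,
                    rng: np.random.Generator) -> tuple[np.ndarray, list[Feature]]:
    """Mutate one lineage at per-site rate q; returns (sequence array,
    features with refreshed translations), in ancestor coordinates."""
    arr = su.encode(genome.sequence)
    if q <= 0:
        return arr, [replace(f) for f in genome.features]
    mask = rng.random(len(arr)) < q
    # protect CDS start + terminal stop codons
    for f in genome.features:
        if f.kind != "CDS":
            continue
        if f.strand == "+":
            mask[f.start : f.start + 3] = False
            mask[f.end - 3 : f.end] = False
        else:
            mask[f.end - 3 : f.end] = False
            mask[f.start : f.start + 3] = False

    shift = rng.integers(1, 4, size=int(mask.sum())).astype(np.uint8)
    arr[mask] = (arr[mask] + shift) % 4

    feats: list[Feature] = []
    for f in genome.features:
        if f.kind != "CDS":
            feats.append(replace(f))
            continue
        sub = arr[f.start : f.end]
        oriented = sub if f.strand == "+" else 3 - sub[::-1]
        omask = mask[f.start : f.end]
        omask = omask if f.strand == "+" else omask[::-1]
        _fix_premature_stops(oriented, omask, rng)
        arr[f.start : f.end] = oriented if f.strand == "+" else 3 - oriented[::-1]
        feats.append(replace(f, protein=su.translate(su.decode(oriented))))
    return arr, feats


def _fix_premature_stops(oriented: np.ndarray, omask: np.ndarray,
                         rng: np.random.Generator) -> None:
    """Resample mutated bases of internal codons that became stops."""
    n_codon = len(oriented) // 3
    cod = oriented[: 3 * n_codon].reshape(-1, 3)
    m = omask[: 3 * n_codon].reshape(-1, 3)
    while True:
        is_stop = (
            (cod[:, 0] == 3)
            & (((cod[:, 1] == 0) & ((cod[:, 2] == 0) | (cod[:, 2] == 2)))
               | ((cod[:, 1] == 2) & (cod[:, 2] == 0)))
        )
        is_stop[0] = False
        is_stop[-1] = False
        bad = np.flatnonzero(is_stop & m.any(axis=1))
        if len(bad) == 0:
            break
        for c in bad:
            muts = np.flatnonzero(m[c])
            pos = int(rng.choice(muts))
            cod[c, pos] = (cod[c, pos] + rng.integers(1, 4)) % 4


# ---------------------------------------------------------------------------
# structural events


@dataclass
class _Edit:
    """One structural edit in ancestor coordinates."""

    kind: str  # insertion | deletion | divergent_replacement | translocation
    genome: str  # "A" | "B"
    start: int  # ancestor coordinate of the edited interval (point for insertion)
    end: int
    new_seq: np.ndarray | None = None  # island / replacement payload
    new_features: list[Feature] | None = None  # in payload-local coordinates
    dest: int | None = None  # translocation destination (ancestor coordinate)


def _intergenic_points(genome: AnnotatedGenome) -> list[int]:
    """Midpoints of intergenic gaps, candidate insertion sites."""
    pts = []
    prev = 0
    for f in genome.features:
        if f.start - prev >= 20:
            pts.append((prev + f.start) // 2)
        prev = max(prev, f.end)
    if len(genome) - prev >= 20:
        pts.append((prev + len(genome)) // 2)
    return pts


def _gene_runs(genome: AnnotatedGenome, n_genes: int) -> list[tuple[int, int, int]]:
    """Candidate feature-bearing intervals spanning n_genes adjacent CDS,
    with boundaries placed mid-intergenic.  Returns (start, end, first_idx)."""
    cds = genome.cds
    out = []
    for i in range(len(cds) - n_genes + 1):
        first, last = cds[i], cds[i + n_genes - 1]
        left = 0 if i == 0 else (cds[i - 1].end + first.start) // 2
        right = (len(genome) if i + n_genes == len(cds)
                 else (last.end + cds[i + n_genes].start) // 2)
        if left < right:
            out.append((left, right, i))
    return out


def _make_segment(length: int, gc: float, marker_prob: float, prefix: str,
                  rng: np.random.Generator,
                  mark_mobility: bool) -> tuple[np.ndarray, list[Feature]]:
    """A gene-bearing payload segment (island or divergent replacement)."""
    seq = su.random_sequence(length, gc, rng)
    feats: list[Feature] = []
    pos = 60
    n = 0
    while pos + 450 + 60 <= length:
        ln = int(rng.integers(120, min(600, length - pos - 60)))
        ln -= ln % 3
        if ln < 120:
            break
        n += 1
        strand = "+" if rng.random() < 0.5 else "-"
        oriented = _gene_arrays(ln, gc, rng)
        seq[pos : pos + ln] = oriented if strand == "+" else 3 - oriented[::-1]
        mobile = mark_mobility and rng.random() < marker_prob
        feats.append(Feature(
            feature_id=f"{prefix}_{n:03d}", kind="CDS", start=pos, end=pos + ln,
            strand=strand,
            product=("transposase" if mobile else f"{prefix} protein {n}"),
            ko=[TRANSPOSASE_KO] if mobile else [],
            cog=[TRANSPOSASE_COG] if mobile else [],
            protein=su.translate(su.decode(oriented)),
        ))
        pos += ln + int(rng.integers(40, 120))
    return seq, feats


def _disjoint(intervals: list[tuple[int, int]], start: int, end: int,
              spacing: int) -> bool:
    return all(end + spacing <= s or e + spacing <= start
               for s, e in intervals)


def _plan_edits(ancestor: AnnotatedGenome, events: EventSpec,
                rng: np.random.Generator) -> list[_Edit]:
    """Choose disjoint event loci on the ancestor and build edit payloads."""
    taken: list[tuple[int, int]] = []
    edits: list[_Edit] = []
    points = _intergenic_points(ancestor)
    rng.shuffle(points)
    gc_island = min(0.95, ancestorspec_gc(ancestor) + events.island_gc_offset)

    def claim_point() -> int:
        for _ in range(200):
            if not points:
                break
            p = points.pop()
            if _disjoint(taken, p, p, events.min_event_spacing):
                taken.append((p, p))
                return p
        raise ValueError("event intervals exhaust the genome: no free insertion point")

    def claim_run(n_genes: int) -> tuple[int, int]:
        runs = _gene_runs(ancestor, n_genes)
        rng.shuffle(runs)
        for s, e, _ in runs:
            if _disjoint(taken, s, e, events.min_event_spacing):
                taken.append((s, e))
                return s, e
        raise ValueError("event intervals exhaust the genome: no free gene run")

    which = rng.permutation(
        ["A", "B"] * ((events.n_insertions + events.n_deletions
                       + events.n_divergent + events.n_translocations) // 2 + 1)
    ).tolist()

    for i in range(events.n_insertions):
        p = claim_point()
        ln = int(rng.integers(events.island_length_range[0],
                              events.island_length_range[1] + 1))
        seq, feats = _make_segment(ln, gc_island, events.mobility_marker_prob,
                                   f"isl{i + 1}", rng, mark_mobility=True)
        edits.append(_Edit("insertion", which.pop(), p, p, seq, feats))

    for _ in range(events.n_deletions):
        n_genes = int(rng.integers(events.deletion_genes[0],
                                   events.deletion_genes[1] + 1))
        s, e = claim_run(n_genes)
        edits.append(_Edit("deletion", which.pop(), s, e))

    for i in range(events.n_divergent):
        s, e = claim_run(int(rng.integers(1, 4)))
        ln = max(600, int((e - s) * rng.uniform(0.8, 1.2)))
        seq, feats = _make_segment(ln, ancestorspec_gc(ancestor), 0.0,
                                   f"div{i + 1}", rng, mark_mobility=False)
        edits.append(_Edit("divergent_replacement", which.pop(), s, e, seq, feats))

    for _ in range(events.n_translocations):
        # a feature-bearing block, moved to a distant intergenic point
        for _ in range(200):
            runs = _gene_runs(ancestor, 1)
            s0, _, i0 = runs[int(rng.integers(0, len(runs)))]
            e0 = s0 + events.translocation_length
            cand = [s for s, e, _ in runs
                    if abs(((s + e) / 2) - (s0 + e0) / 2) >= events.translocation_offset]
            if e0 >= len(ancestor) or not cand:
                continue
            # snap end to mid-intergenic
            ends = [e for _, e, _ in _gene_runs(ancestor, 1)
                    if s0 < e <= e0 + 2000]
            if not ends:
                continue
            e0 = max(ends)
            dest = int(rng.choice(cand))
            if (_disjoint(taken, s0, e0, events.min_event_spacing)
                    and _disjoint(taken, dest, dest, events.min_event_spacing)):
                taken.append((s0, e0))
                taken.append((dest, dest))
                edits.append(_Edit("translocation", which.pop(), s0, e0, dest=dest))
                break
        else:
            raise ValueError("event intervals exhaust the genome: "
                             "no admissible translocation block")
    return edits


def ancestorspec_gc(genome: AnnotatedGenome) -> float:
    s = genome.sequence
    return (s.count("G") + s.count("C")) / max(1, len(s))


class _CoordMap:
    """Piecewise ancestor -> final coordinate map built during emission."""

    def __init__(self) -> None:
        self.pieces: list[tuple[int, int, int]] = []  # (anc_start, anc_end, out_start)

    def add(self, anc_start: int, anc_end: int, out_start: int) -> None:
        if anc_end > anc_start:
            self.pieces.append((anc_start, anc_end, out_start))

    def map_interval(self, start: int, end: int) -> tuple[int, int] | None:
        """Map an ancestor interval fully contained in one piece."""
        for s, e, o in self.pieces:
            if start >= s and end <= e:
                return (o + start - s, o + end - s)
        return None


def _apply_edits(seq: np.ndarray, feats: list[Feature], edits: list[_Edit],
                 genome_label: str) -> tuple[np.ndarray, list[Feature], _CoordMap,
                                             dict[int, tuple[int, int]]]:
    """Apply this genome's edits; returns final sequence, features, the
    ancestor->final coordinate map and per-edit final intervals."""
    mine = sorted((e for e in edits if e.genome == genome_label),
                  key=lambda e: e.start)
    # translocation = deletion at source + insertion of the (mutated) block
    ops: list[tuple[int, int, str, _Edit | None, np.ndarray | None,
                    list[Feature] | None]] = []
    for e in mine:
        if e.kind == "translocation":
            block_seq = seq[e.start : e.end].copy()
            block_feats = [f.shifted(-e.start) for f in feats
                           if f.start >= e.start and f.end <= e.end]
            ops.append((e.start, e.end, "delete", None, None, None))
            ops.append((e.dest, e.dest, "insert_block", e, block_seq, block_feats))
        elif e.kind == "insertion":
            ops.append((e.start, e.end, "insert", e, e.new_seq, e.new_features))
        elif e.kind == "deletion":
            ops.append((e.start, e.end, "delete", e, None, None))
        else:  # divergent_replacement
            ops.append((e.start, e.end, "replace", e, e.new_seq, e.new_features))
    ops.sort(key=lambda t: (t[0], t[1]))

    out_parts: list[np.ndarray] = []
    out_feats: list[Feature] = []
    cmap = _CoordMap()
    edit_spans: dict[int, tuple[int, int]] = {}
    cursor = 0
    out_len = 0

    def emit_ancestral(upto: int) -> None:
        nonlocal cursor, out_len
        if upto > cursor:
            out_parts.append(seq[cursor:upto])
            cmap.add(cursor, upto, out_len)
            for f in feats:
                if f.start >= cursor and f.end <= upto:
                    out_feats.append(f.shifted(out_len - cursor))
            out_len += upto - cursor
        cursor = upto

    for s, e, op, edit, payload, pfeats in ops:
        emit_ancestral(s)
        if op == "delete":
            cursor = e
            continue
        span_start = out_len
        out_parts.append(payload)
        for f in pfeats:
            out_feats.append(f.shifted(out_len))
        out_len += len(payload)
        if edit is not None:
            edit_spans[id(edit)] = (span_start, out_len)
        cursor = e
    emit_ancestral(len(seq))

    final = np.concatenate(out_parts) if out_parts else np.empty(0, dtype=np.uint8)
    out_feats.sort(key=lambda f: f.start)
    return final, out_feats, cmap, edit_spans


def evolve_pair(ancestor: AnnotatedGenome, events: EventSpec
                ) -> tuple[AnnotatedGenome, AnnotatedGenome, TruthLog]:
    """Evolve the ancestor into two derived genomes plus the truth log."""
    events.validate()
    rng = np.random.default_rng(events.rng_seed)
    rng_a, rng_b, rng_s = rng.spawn(3)

    q = per_lineage_rate(events.substitution_rate)
    seq_a, feats_a = _mutate_lineage(ancestor, q, rng_a)
    seq_b, feats_b = _mutate_lineage(ancestor, q, rng_b)
    # lineage-specific locus tags
    feats_a = [replace(f, feature_id=f.feature_id.replace("anc_", "A_"))
               for f in feats_a]
    feats_b = [replace(f, feature_id=f.feature_id.replace("anc_", "B_"))
               for f in feats_b]

    edits = _plan_edits(ancestor, events, rng_s)

    fa, ofa, map_a, spans_a = _apply_edits(seq_a, feats_a, edits, "A")
    fb, ofb, map_b, spans_b = _apply_edits(seq_b, feats_b, edits, "B")

    log = TruthLog()
    if events.substitution_rate > 0:
        log.events.append(TruthEvent("substitution_bulk", "A"))
        log.events.append(TruthEvent("substitution_bulk", "B"))

    for e in edits:
        own_spans = spans_a if e.genome == "A" else spans_b
        other_map = map_b if e.genome == "A" else map_a

        if e.kind == "insertion":
            span = own_spans[id(e)]
            ids = [f.feature_id for f in (e.new_features or [])]
            a_iv, b_iv = (span, None) if e.genome == "A" else (None, span)
            log.events.append(TruthEvent("insertion", e.genome, a_iv, b_iv, ids))
        elif e.kind == "deletion":
            other = other_map.map_interval(e.start, e.end)
            a_iv, b_iv = (None, other) if e.genome == "A" else (other, None)
            feats_other = ofb if e.genome == "A" else ofa
            ids = ([f.feature_id for f in feats_other
                    if other and f.start >= other[0] and f.end <= other[1]])
            log.events.append(TruthEvent("deletion", e.genome, a_iv, b_iv, ids))
        elif e.kind == "divergent_replacement":
            span = own_spans[id(e)]
            other = other_map.map_interval(e.start, e.end)
            a_iv, b_iv = (span, other) if e.genome == "A" else (other, span)
            ids = [f.feature_id for f in (e.new_features or [])]
            log.events.append(
                TruthEvent("divergent_replacement", e.genome, a_iv, b_iv, ids))
        else:  # translocation
            span = own_spans[id(e)]
            other = other_map.map_interval(e.start, e.end)
            a_iv, b_iv = (span, other) if e.genome == "A" else (other, span)
            log.events.append(TruthEvent("translocation", e.genome, a_iv, b_iv))

    genome_a = AnnotatedGenome(f"{ancestor.genome_id}_A", su.decode(fa), ofa)
    genome_b = AnnotatedGenome(f"{ancestor.genome_id}_B", su.decode(fb), ofb)
    return genome_a, genome_b, log


def write_fixture(pair: tuple[AnnotatedGenome, AnnotatedGenome], truth: TruthLog,
                  directory) -> dict[str, str]:
    """Write the pair + truth log as FASTA/GFF3/CSV files; returns paths."""
    from pathlib import Path
    from . import io as sio
    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = {}
    for g in pair:
        written[f"{g.genome_id}.fna"] = str(directory / f"{g.genome_id}.fna")
        sio.write_fasta([(g.genome_id, g.sequence)], directory / f"{g.genome_id}.fna")
        prots = [(fid, seq) for fid, seq in g.proteome().items()]
        sio.write_fasta(prots, directory / f"{g.genome_id}.faa")
        written[f"{g.genome_id}.faa"] = str(directory / f"{g.genome_id}.faa")
        sio.write_gff3(g, directory / f"{g.genome_id}.gff3")
        written[f"{g.genome_id}.gff3"] = str(directory / f"{g.genome_id}.gff3")
        sio.write_annotation_table(g, directory / f"{g.genome_id}_annotations.csv")
        written[f"{g.genome_id}_annotations.csv"] = str(
            directory / f"{g.genome_id}_annotations.csv")

    rows = []
    for e in truth.events:
        rows.append({
            "event_type": e.event_type,
            "genome": e.genome,
            "a_start": e.a_interval[0] + 1 if e.a_interval else "",
            "a_end": e.a_interval[1] if e.a_interval else "",
            "b_start": e.b_interval[0] + 1 if e.b_interval else "",
            "b_end": e.b_interval[1] if e.b_interval else "",
            "payload_ids": ";".join(e.payload_ids),
        })
    truth_path = directory / "truth.csv"
    pd.DataFrame(rows, columns=["event_type", "genome", "a_start", "a_end",
                                "b_start", "b_end", "payload_ids"]
                 ).to_csv(truth_path, index=False)
    written["truth.csv"] = str(truth_path)
    return written
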