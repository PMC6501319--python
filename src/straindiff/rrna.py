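"""Multi-copy 16S rRNA heterogeneity: alignment, consensus masking, regions.

Bacterial genomes usually carry several near-identical 16S rRNA gene
copies.  When the locus is Sanger-sequenced in bulk, a variant present in a
single copy is hidden by the majority signal ("consensus masking") and the
read-out shows the majority base.  This module aligns the copies (a
progressive pairwise global aligner, adequate for >99%-identical copies; not
a general MSA tool), tabulates per-column variants, flags masked positions
(exactly one copy deviating from the agreeing rest), and maps hypervariable
region coordinates (e.g. V1–V9 defined on an external reference row) onto
alignment columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import Align

IUPAC_AMBIGUITY = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GT"): "K",
    frozenset("AC"): "M", frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("CGT"): "B", frozenset("ACG"): "V", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACGT"): "N",
}


@dataclass
class CopyAlignment:
    ids: list[str]
    rows: list[str]  # equal-length gapped rows

    def __post_init__(self) -> None:
        lens = {len(r) for r in self.rows}
        if len(lens) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, row_id: str) -> str:
        return self.rows[self.ids.index(row_id)]


def _pairwise_aligner() -> Align.PairwiseAligner:
    # scores tuned for near-identical sequences, not remote homology
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 2
    a.mismatch_score = -3
    a.open_gap_score = -5
    a.extend_gap_score = -2
    return a


def align_copies(copies: list[tuple[str, str]]) -> CopyAlignment:
    """Centre-star progressive global alignment of near-identical gene
    copies.  Each copy is pairwise-aligned to the first copy (the centre);
    the pairwise alignments are merged on the centre's ungapped coordinate
    system, with insertions relative to the centre padded to their maximum
    length across copies.  Identical copies collapse to identical rows.
    Copies must number >= 2 and have lengths within 10% of each other."""
    if len(copies) < 2:
        raise ValueError("need >= 2 copies to align")
    lengths = [len(s) for _, s in copies]
    if max(lengths) > 1.1 * min(lengths):
        raise ValueError("copy lengths differ by more than 10%")
    aligner = _pairwise_aligner()

    center_id, center = copies[0]
    center = center.upper()
    n = len(center)
    # per copy: aligned base at each centre position, and the insertion
    # string placed before each centre position (key n = after the end)
    profiles: dict[str, tuple[list[str], dict[int, str]]] = {}
    for cid, seq in copies[1:]:
        profiles[cid] = _profile_against_center(aligner, center, seq.upper())

    ins_len = {j: 0 for j in range(n + 1)}
    for _, ins in profiles.values():
        for j, s in ins.items():
            ins_len[j] = max(ins_len[j], len(s))

    ids = [cid for cid, _ in copies]
    rows: dict[str, list[str]] = {cid: [] for cid in ids}
    for j in range(n + 1):
        if ins_len[j]:
            rows[center_id].append("-" * ins_len[j])
            for cid in ids[1:]:
                s = profiles[cid][1].get(j, "")
                rows[cid].append(s.ljust(ins_len[j], "-"))
        if j < n:
            rows[center_id].append(center[j])
            for cid in ids[1:]:
                rows[cid].append(profiles[cid][0][j])
    return CopyAlignment(ids, ["".join(rows[cid]) for cid in ids])


def _profile_against_center(aligner, center: str, seq: str
                            ) -> tuple[list[str], dict[int, str]]:
    """Pairwise global alignment of one copy against the centre, expressed
    as (aligned base per centre position, insertions before each centre
    position)."""
    aln = aligner.align(center, seq)[0]
    aligned = ["-"] * len(center)
    ins: dict[int, str] = {}
    tpos = qpos = 0
    for (t0, t1), (q0, q1) in zip(aln.aligned[0], aln.aligned[1]):
        if q0 > qpos:  # insertion in the copy before centre position t0
            ins[t0] = ins.get(t0, "") + seq[qpos:q0]
        tpos, qpos = t0, q0
        for k in range(t1 - t0):
            aligned[t0 + k] = seq[q0 + k]
        tpos, qpos = t1, q1
    if qpos < len(seq):  # trailing insertion
        ins[len(center)] = ins.get(len(center), "") + seq[qpos:]
    return aligned, ins


# ---------------------------------------------------------------------------
# variants and masking


@dataclass
class VariantColumn:
    column: int  # 1-based alignment column
    states: dict[str, str]  # copy id -> base (or '-')
    consensus: str
    masked: bool
    tied: bool = False
    region: str | None = None


@dataclass
class CopyVariantReport:
    variants: list[VariantColumn]
    consensus: str
    per_copy_differences: dict[str, int]

    def masked_columns(self) -> list[int]:
        return [v.column for v in self.variants if v.masked]


def copy_variants(alignment: CopyAlignment,
                  copy_ids: list[str] | None = None) -> CopyVariantReport:
    """Per-column variant table, majority consensus and masked flags.

    ``masked`` marks columns where exactly one copy deviates from the
    (agreeing) others — the situation in which bulk sequencing of the locus
    reports the majority base and hides the variant.  Consensus ties emit
    IUPAC ambiguity codes and are flagged.  Rows not in ``copy_ids``
    (external comparator sequences) are excluded from the consensus."""
    if copy_ids is None:
        copy_ids = list(alignment.ids)
    rows = {cid: alignment.row(cid) for cid in copy_ids}
    n_cols = alignment.n_columns
    variants: list[VariantColumn] = []
    consensus_chars: list[str] = []
    diffs = {cid: 0 for cid in copy_ids}

    for col in range(n_cols):
        states = {cid: rows[cid][col] for cid in copy_ids}
        bases = list(states.values())
        counts: dict[str, int] = {}
        for b in bases:
            counts[b] = counts.get(b, 0) + 1
        top = max(counts.values())
        winners = sorted(b for b, c in counts.items() if c == top)
        tied = len(winners) > 1
        if tied:
            letters = frozenset(b for b in winners if b != "-") or frozenset("N")
            consensus = IUPAC_AMBIGUITY.get(letters, "N")
        else:
            consensus = winners[0]
        consensus_chars.append(consensus)
        if len(set(bases)) > 1:
            deviants = [cid for cid, b in states.items() if b != consensus]
            masked = (not tied and len(deviants) == 1)
            for cid in deviants:
                diffs[cid] += 1
            variants.append(VariantColumn(col + 1, states, consensus,
                                          masked, tied))
    return CopyVariantReport(variants, "".join(consensus_chars), diffs)


def map_regions(alignment: CopyAlignment, reference_id: str,
                region_coords: list[tuple[str, int, int]]
                ) -> dict[int, str]:
    """Label alignment columns with named sub-regions (e.g. hypervariable
    regions V1–V9) given 1-based inclusive coordinates on the *ungapped*
    reference row.  Gap columns of the reference inherit no label.
    Returns {1-based column: region name}."""
    ref_row = alignment.row(reference_id)
    ref_len = sum(1 for c in ref_row if c != "-")
    for name, start, end in region_coords:
        if start < 1 or end > ref_len:
            raise ValueError(f"region {name} [{start},{end}] outside the "
                             f"reference length {ref_len}")
    labels: dict[int, str] = {}
    ref_pos = 0
    for col, c in enumerate(ref_row, start=1):
        if c == "-":
            continue
        ref_pos += 1
        for name, start, end in region_coords:
            if start <= ref_pos <= end:
                labels[col] = name
                break
    return labels


def annotate_variants(report: CopyVariantReport,
                      labels: dict[int, str]) -> None:
    for v in report.variants:
        v.region = labels.get(v.column)


def variants_to_dataframe(report: CopyVariantReport) -> pd.DataFrame:
    rows = []
    for v in report.variants:
        row = {"column": v.column, "consensus": v.consensus,
               "masked": v.masked, "tied": v.tied, "region": v.region or ""}
        row.update({f"copy_{cid}": b for cid, b in v.states.items()})
        rows.append(row)
    return pd.DataFrame(rows)
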