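"""Protein best-hit orthology, presence matrices, synteny and ANIb.

Orthology follows the classic one-directional best-hit protocol: every query
protein is locally aligned (Smith–Waterman, BLOSUM62 by default) against the
subject proteome, hits with query coverage < 80% or e-value > 1e-5 are
discarded, and the best remaining hit by bit score is retained (ties broken
by lower e-value, then lexicographic subject id).  E-values use ungapped
Karlin–Altschul statistics applied to the gapped score — a documented
approximation; precomputed 12-column tabular hits can be ingested instead
for exact replication of an external search tool.

ANIb fragments genome A into consecutive 1020-bp pieces, aligns each to
genome B on both strands, retains fragments with >= 30% identity over
>= 70% of their length, and averages the retained identities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import edlib
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .genome import AnnotatedGenome, revcomp
from .io import TabularHit
from .regions import RegionCall

# ungapped Karlin–Altschul parameters per scoring matrix
KA_PARAMS = {"BLOSUM62": (0.3176, 0.134), "BLOSUM45": (0.2291, 0.0924),
             "BLOSUM80": (0.3430, 0.177)}

DEFAULT_MIN_COVERAGE = 80.0
DEFAULT_MAX_E = 1e-5


@dataclass
class ProteinAlignment:
    """One scored local alignment of a query against a subject."""

    score: float
    identity: float  # percent of alignment columns
    similarity: float  # percent of columns with positive substitution score
    query_coverage: float  # percent of query length spanned
    e_value: float
    bit_score: float
    n_columns: int


@dataclass
class OrthologPair:
    query_id: str
    subject_id: str
    query_coverage: float
    identity: float
    similarity: float
    e_value: float
    bit_score: float
    collinear: bool | None = None

    def __post_init__(self) -> None:
        if self.similarity < self.identity - 1e-9:
            raise ValueError(f"{self.query_id}: similarity {self.similarity} "
                             f"< identity {self.identity}")


def _aligner(matrix_name: str, gap_open: float, gap_extend: float
             ) -> Align.PairwiseAligner:
    try:
        matrix = substitution_matrices.load(matrix_name)
    except FileNotFoundError:
        raise ValueError(f"unknown substitution matrix {matrix_name!r}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def align_proteins_local(query: str, subject: str,
                         matrix_name: str = "BLOSUM62",
                         gap_open: float = 11.0, gap_extend: float = 1.0,
                         db_size: int | None = None
                         ) -> ProteinAlignment | None:
    """Optimal local alignment with identity/similarity/coverage and a
    Karlin–Altschul e-value.  Returns ``None`` when the best score is
    non-positive ("no hit").  ``db_size`` (total subject residues) scales the
    e-value search space; defaults to ``len(subject)``.
    """
    if not query or not subject:
        raise ValueError("protein sequences must be non-empty")
    if matrix_name not in KA_PARAMS:
        raise ValueError(f"unknown matrix {matrix_name!r}; "
                         f"choose from {sorted(KA_PARAMS)}")
    aligner = _aligner(matrix_name, gap_open, gap_extend)
    matrix = aligner.substitution_matrix
    # co-optimal paths all share the optimal score; the first suffices
    alignments = aligner.align(query, subject)
    try:
        if len(alignments) == 0:
            return None
    except OverflowError:
        pass  # astronomically many co-optimal paths; certainly non-empty
    best = alignments[0]
    if best.score <= 0:
        return None

    qa, sa = best.aligned  # aligned segment coordinates
    matches = positives = aligned_cols = 0
    for (q0, q1), (s0, s1) in zip(qa, sa):
        for q, s in zip(query[q0:q1], subject[s0:s1]):
            aligned_cols += 1
            if q == s:
                matches += 1
            try:
                if matrix[q, s] > 0:
                    positives += 1
            except KeyError:
                pass
    # columns include internal gaps
    gap_cols = 0
    for (pq, ps), (nq, ns) in zip(zip(qa[:-1], sa[:-1]), zip(qa[1:], sa[1:])):
        gap_cols += max(nq[0] - pq[1], ns[0] - ps[1])
    n_columns = aligned_cols + gap_cols
    q_span = qa[-1][1] - qa[0][0]

    lam, k = KA_PARAMS[matrix_name]
    n = db_size if db_size is not None else len(subject)
    e_value = k * len(query) * n * float(np.exp(-lam * best.score))
    bit_score = (lam * best.score - float(np.log(k))) / float(np.log(2))
    return ProteinAlignment(
        score=float(best.score),
        identity=100.0 * matches / n_columns,
        similarity=100.0 * positives / n_columns,
        query_coverage=100.0 * q_span / len(query),
        e_value=e_value,
        bit_score=bit_score,
        n_columns=n_columns,
    )


# ---------------------------------------------------------------------------
# best hits


def _kmer_index(proteome: dict[str, str], k: int) -> dict[str, set[str]]:
    index: dict[str, set[str]] = {}
    for pid, seq in proteome.items():
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i:i + k], set()).add(pid)
    return index


def _candidates(query: str, index: dict[str, set[str]], k: int) -> set[str]:
    cands: set[str] = set()
    for i in range(len(query) - k + 1):
        cands |= index.get(query[i:i + k], set())
    return cands


def best_hits(proteome_a: dict[str, str], proteome_b: dict[str, str],
              min_coverage: float = DEFAULT_MIN_COVERAGE,
              max_e: float = DEFAULT_MAX_E,
              matrix_name: str = "BLOSUM62",
              prefilter_k: int = 5) -> list[OrthologPair]:
    """One-directional best hits of every protein in ``proteome_a`` against
    ``proteome_b``.  A shared-``prefilter_k``-mer screen skips hopeless
    pairs; queries without a passing hit are simply absent from the result.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("proteomes must be non-empty")
    db_size = sum(len(s) for s in proteome_b.values())
    index = _kmer_index(proteome_b, prefilter_k)
    pairs: list[OrthologPair] = []
    for qid in sorted(proteome_a):
        query = proteome_a[qid]
        best: tuple | None = None
        for sid in sorted(_candidates(query, index, prefilter_k)):
            aln = align_proteins_local(query, proteome_b[sid],
                                       matrix_name, db_size=db_size)
            if aln is None:
                continue
            if aln.query_coverage < min_coverage or aln.e_value > max_e:
                continue
            key = (-aln.bit_score, aln.e_value, sid)
            if best is None or key < best[0]:
                best = (key, sid, aln)
        if best is not None:
            _, sid, aln = best
            pairs.append(OrthologPair(qid, sid, aln.query_coverage,
                                      aln.identity, aln.similarity,
                                      aln.e_value, aln.bit_score))
    return pairs


def best_hits_from_table(hits: list[TabularHit],
                         query_lengths: dict[str, int],
                         min_coverage: float = DEFAULT_MIN_COVERAGE,
                         max_e: float = DEFAULT_MAX_E) -> list[OrthologPair]:
    """Best-hit selection over precomputed tabular hits (the recommended
    route for exact replication of an external aligner's statistics).
    Query coverage is computed from the aligned query span; similarity is
    unavailable in the 12-column dialect and reported equal to identity."""
    best: dict[str, tuple] = {}
    for h in hits:
        qlen = query_lengths.get(h.query_id)
        if qlen is None:
            raise KeyError(f"no length for query {h.query_id}")
        coverage = 100.0 * (abs(h.q_end - h.q_start) + 1) / qlen
        if coverage < min_coverage or h.e_value > max_e:
            continue
        key = (-h.bit_score, h.e_value, h.subject_id)
        if h.query_id not in best or key < best[h.query_id][0]:
            best[h.query_id] = (key, h, coverage)
    out = []
    for qid in sorted(best):
        _, h, coverage = best[qid]
        out.append(OrthologPair(qid, h.subject_id, coverage,
                                h.percent_identity, h.percent_identity,
                                h.e_value, h.bit_score))
    return out


# ---------------------------------------------------------------------------
# positional collinearity


def positional_orthologs(pairs: list[OrthologPair],
                         regions: list[RegionCall],
                         genome_a: AnnotatedGenome,
                         genome_b: AnnotatedGenome) -> list[OrthologPair]:
    """Flag each ortholog pair as collinear iff both genes lie in the same
    collinear region (block-homologous position)."""

    def locate(genome: AnnotatedGenome, which: str, fid: str) -> RegionCall | None:
        f = genome.feature_by_id(fid)  # KeyError for unknown ids
        mid = f.midpoint
        for r in regions:
            iv = r.a_interval if which == "A" else r.b_interval
            if iv and iv[0] <= mid < iv[1]:
                return r
        return None

    out = []
    for p in pairs:
        ra = locate(genome_a, "A", p.query_id)
        rb = locate(genome_b, "B", p.subject_id)
        collinear = (ra is not None and ra is rb
                     and ra.region_class == "collinear")
        out.append(replace(p, collinear=collinear))
    return out


# ---------------------------------------------------------------------------
# presence matrix and region summaries


def homolog_presence_matrix(gene_set: dict[str, str],
                            proteomes: dict[str, dict[str, str]],
                            min_coverage: float = DEFAULT_MIN_COVERAGE,
                            max_e: float = DEFAULT_MAX_E) -> pd.DataFrame:
    """genes x organisms boolean matrix: present iff >= 1 hit passes the
    coverage/e-value thresholds in that organism's proteome."""
    if not gene_set or not proteomes:
        raise ValueError("need at least one gene and one proteome")
    data = {}
    for org, proteome in proteomes.items():
        if not proteome:
            data[org] = {g: False for g in gene_set}
            continue
        hits = best_hits(gene_set, proteome, min_coverage, max_e)
        found = {h.query_id for h in hits}
        data[org] = {g: g in found for g in gene_set}
    return pd.DataFrame(data).loc[list(gene_set)]


@dataclass
class RegionHomologySummary:
    n_genes: int
    n_with_homolog: int
    mean_coverage: float | None
    mean_similarity: float | None


def region_homology_summary(gene_set: dict[str, str],
                            proteome: dict[str, str],
                            min_coverage: float = DEFAULT_MIN_COVERAGE,
                            max_e: float = DEFAULT_MAX_E
                            ) -> RegionHomologySummary:
    """Mean best-hit coverage/similarity over the genes of one region that
    have a passing homolog in the proteome."""
    hits = best_hits(gene_set, proteome, min_coverage, max_e) if proteome else []
    if not hits:
        return RegionHomologySummary(len(gene_set), 0, None, None)
    return RegionHomologySummary(
        n_genes=len(gene_set),
        n_with_homolog=len(hits),
        mean_coverage=float(np.mean([h.query_coverage for h in hits])),
        mean_similarity=float(np.mean([h.similarity for h in hits])),
    )


# ---------------------------------------------------------------------------
# gene-order (synteny) comparison


@dataclass
class SyntenyComparison:
    matches: list[tuple[int, int]]  # (index in A order, index in B order)
    unmatched_a: list[int]
    unmatched_b: list[int]
    breakpoints: int
    inversions: int


def region_synteny(region_a_genes: list[str], region_b_genes: list[str],
                   pairs: list[OrthologPair]) -> SyntenyComparison:
    """Compare gene order between two homologous regions.

    A breakpoint is an adjacency (in A order) of two matched genes whose B
    indices are not consecutive (|Δ| != 1); an inversion is a maximal run of
    descending consecutive B indices.
    """
    link = {p.query_id: p.subject_id for p in pairs}
    b_index = {g: i for i, g in enumerate(region_b_genes)}
    matches = []
    unmatched_a = []
    for i, g in enumerate(region_a_genes):
        j = b_index.get(link.get(g, ""), None)
        if j is None:
            unmatched_a.append(i)
        else:
            matches.append((i, j))
    matched_b = {j for _, j in matches}
    unmatched_b = [j for j in range(len(region_b_genes)) if j not in matched_b]

    bs = [j for _, j in matches]
    breakpoints = sum(1 for x, y in zip(bs, bs[1:]) if abs(y - x) != 1)
    inversions = 0
    in_desc = False
    for x, y in zip(bs, bs[1:]):
        if y - x == -1:
            if not in_desc:
                inversions += 1
            in_desc = True
        else:
            in_desc = False
    return SyntenyComparison(matches, unmatched_a, unmatched_b,
                             breakpoints, inversions)


# ---------------------------------------------------------------------------
# ANIb


@dataclass
class ANIResult:
    ani: float | None  # percent; None when unalignable
    n_fragments: int
    n_retained: int

    @property
    def unalignable(self) -> bool:
        return self.ani is None

    @property
    def low_support(self) -> bool:
        return self.n_fragments > 0 and self.n_retained < 0.2 * self.n_fragments


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    out = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append((int(num), ch))
            num = ""
    return out


def _best_local_segment(runs: list[tuple[int, str]]
                        ) -> tuple[int, int, int]:
    """(matches, columns, query columns) of the maximum-scoring contiguous
    segment of an alignment path under +1 match / -2 difference scoring —
    a local-alignment view of a semi-global edit path.  Spurious alignments
    of unrelated sequence leave only short positive segments."""
    best = (0, 0, 0)
    best_score = 0.0
    score = 0.0
    cur = [0, 0, 0]  # matches, columns, query columns
    for n, op in runs:
        delta = n if op == "=" else -2 * n
        if score + delta < 0:
            score = 0.0
            cur = [0, 0, 0]
            continue
        score += delta
        cur[0] += n if op == "=" else 0
        cur[1] += n
        cur[2] += n if op in "=XI" else 0
        if score > best_score:
            best_score = score
            best = tuple(cur)
    return best


def _fragment_identity(frag: str, target: str, min_identity: float,
                       min_fragment_fraction: float) -> float | None:
    """Best-strand identity (percent) of one fragment's retained alignment,
    or None when no alignment passes the retention rule (identity >=
    ``min_identity`` over >= ``min_fragment_fraction`` of the fragment,
    judged on the best local segment of the edit path).  A cheap
    low-divergence pass runs first; the expensive high-divergence cap only
    runs when neither strand hits."""
    results = []
    for q in (frag, revcomp(frag)):
        results.append((q, edlib.align(q, target, mode="HW", task="path",
                                       k=int(len(frag) * 0.25))))
    if all(r["editDistance"] < 0 for _, r in results):
        results = [(q, edlib.align(q, target, mode="HW", task="path",
                                   k=int(len(frag) * 0.75)))
                   for q, _ in results]
    best = None
    for q, res in results:
        if res["editDistance"] < 0:
            continue
        matches, cols, qcols = _best_local_segment(_parse_cigar(res["cigar"]))
        if cols == 0 or qcols < min_fragment_fraction * len(frag):
            continue
        ident = 100.0 * matches / cols
        if ident < min_identity:
            continue
        if best is None or ident > best:
            best = ident
    return best


def compute_anib(genome_a, genome_b, fragment_length: int = 1020,
                 min_identity: float = 30.0, min_fragment_fraction: float = 0.7
                 ) -> ANIResult:
    """One-directional ANIb: fragment A, align to B (both strands), retain
    fragments with identity >= min_identity over >= min_fragment_fraction of
    their length, average retained identities."""
    seq_a = genome_a.sequence if isinstance(genome_a, AnnotatedGenome) else genome_a
    seq_b = genome_b.sequence if isinstance(genome_b, AnnotatedGenome) else genome_b
    if len(seq_a) < fragment_length:
        raise ValueError("genome A shorter than the fragment length")
    identities = []
    n_fragments = 0
    for start in range(0, len(seq_a) - fragment_length + 1, fragment_length):
        frag = seq_a[start:start + fragment_length]
        n_fragments += 1
        ident = _fragment_identity(frag, seq_b, min_identity,
                                   min_fragment_fraction)
        if ident is not None and ident >= min_identity:
            identities.append(ident)
    if not identities:
        return ANIResult(None, n_fragments, 0)
    return ANIResult(float(np.mean(identities)), n_fragments, len(identities))


def compute_anib_symmetric(genome_a, genome_b, **kwargs) -> ANIResult:
    """Mean of the two one-directional ANIb values."""
    ab = compute_anib(genome_a, genome_b, **kwargs)
    ba = compute_anib(genome_b, genome_a, **kwargs)
    if ab.ani is None or ba.ani is None:
        return ANIResult(None, ab.n_fragments + ba.n_fragments,
                         ab.n_retained + ba.n_retained)
    return ANIResult((ab.ani + ba.ani) / 2, ab.n_fragments + ba.n_fragments,
                     ab.n_retained + ba.n_retained)


def orthologs_to_dataframe(pairs: list[OrthologPair]) -> pd.DataFrame:
    return pd.DataFrame([{
        "query": p.query_id, "subject": p.subject_id,
        "coverage": p.query_coverage, "identity": p.identity,
        "similarity": p.similarity, "e_value": p.e_value,
        "bit_score": p.bit_score, "collinear": p.collinear,
    } for p in pairs], columns=["query", "subject", "coverage", "identity",
                                "similarity", "e_value", "bit_score",
                                "collinear"])
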