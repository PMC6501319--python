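"""Functional-annotation deltas, transposase census and the CRISPR test.

Two genomes are compared at the level of their KO/COG annotation
complements: ortholog annotation transfer first reconciles the two tables
(a KO present on exactly one member of an ortholog pair is copied to the
other), then exclusive annotation sets are taken as set differences of the
annotation universes, with transposase markers removed first by default.
Genes carrying exclusive annotations are clustered into genomic regions.

The CRISPR/transposase co-occurrence test asks whether genomes with an
annotated CRISPR locus carry more transposases on average; it is a one-sided
Welch two-sample t-test computed from the textbook formula (sample sds with
n-1 denominators, Welch–Satterthwaite degrees of freedom, upper-tail
Student-t p-value).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import AnnotatedGenome
from .orthology import OrthologPair

logger = logging.getLogger("straindiff.plasticity")

# transposase / putative transposase markers
TRANSPOSASE_KO = ("K07483", "K07497")
TRANSPOSASE_COG = ("COG2801", "COG2963", "COG3328")
TRANSPOSASE_PFAM = ("pfam00872", "pfam01527", "pfam01609", "pfam01797",
                    "pfam02371", "pfam05598", "pfam09299", "pfam12762",
                    "pfam12784")

AnnotationTable = dict[str, dict[str, list[str]]]  # feature_id -> vocab -> ids


def genome_annotation_table(genome: AnnotatedGenome) -> AnnotationTable:
    return {f.feature_id: {"KO": list(f.ko), "COG": list(f.cog),
                           "Pfam": list(f.pfam)}
            for f in genome.features}


def transfer_annotations(table_a: AnnotationTable, table_b: AnnotationTable,
                         orthologs: list[OrthologPair],
                         vocab: str = "KO"
                         ) -> tuple[AnnotationTable, AnnotationTable, list]:
    """Fill-in annotation transfer between ortholog pairs.

    Where exactly one member of a pair carries an annotation in ``vocab``,
    it is copied to the other; conflicting annotations (both present,
    different) are left untouched and returned as logged conflicts.  The
    operation is idempotent and never overwrites."""
    out_a = {k: {v: list(ids) for v, ids in d.items()}
             for k, d in table_a.items()}
    out_b = {k: {v: list(ids) for v, ids in d.items()}
             for k, d in table_b.items()}
    conflicts = []
    for p in orthologs:
        ta = out_a.get(p.query_id)
        tb = out_b.get(p.subject_id)
        if ta is None or tb is None:
            continue
        ids_a, ids_b = set(ta.get(vocab, [])), set(tb.get(vocab, []))
        if ids_a and not ids_b:
            tb[vocab] = sorted(ids_a)
        elif ids_b and not ids_a:
            ta[vocab] = sorted(ids_b)
        elif ids_a and ids_b and ids_a != ids_b:
            conflicts.append((p.query_id, p.subject_id, sorted(ids_a),
                              sorted(ids_b)))
            logger.info("annotation conflict %s=%s vs %s=%s left untouched",
                        p.query_id, sorted(ids_a), p.subject_id, sorted(ids_b))
    return out_a, out_b, conflicts


def _universe(table: AnnotationTable, vocab: str) -> set[str]:
    out: set[str] = set()
    for d in table.values():
        out |= set(d.get(vocab, []))
    return out


def exclusive_annotation_sets(table_a: AnnotationTable,
                              table_b: AnnotationTable,
                              exclude_transposases: bool = True
                              ) -> dict[str, set[str]]:
    """Set differences of the KO and COG annotation universes.

    Returns keys ``ko_only_a``, ``cog_only_a``, ``ko_only_b``,
    ``cog_only_b``.  Transposase marker ids are removed from the universes
    first when ``exclude_transposases`` is set."""
    drop_ko = set(TRANSPOSASE_KO) if exclude_transposases else set()
    drop_cog = set(TRANSPOSASE_COG) if exclude_transposases else set()
    ko_a = _universe(table_a, "KO") - drop_ko
    ko_b = _universe(table_b, "KO") - drop_ko
    cog_a = _universe(table_a, "COG") - drop_cog
    cog_b = _universe(table_b, "COG") - drop_cog
    return {"ko_only_a": ko_a - ko_b, "cog_only_a": cog_a - cog_b,
            "ko_only_b": ko_b - ko_a, "cog_only_b": cog_b - cog_a}


def group_exclusive_regions(exclusive_gene_ids: set[str],
                            genome: AnnotatedGenome,
                            max_gene_gap: int = 2
                            ) -> list[tuple[int, int, list[str]]]:
    """Cluster genes carrying exclusive annotations into regions.

    Genes separated by <= ``max_gene_gap`` intervening genes join one
    region; each region interval spans the first to the last member gene
    (0-based half-open).  Returns (start, end, member_ids) triples."""
    order = [f for f in genome.features if f.kind == "CDS"]
    idx = {f.feature_id: i for i, f in enumerate(order)}
    for g in exclusive_gene_ids:
        if g not in idx:
            raise KeyError(f"gene {g} not found in genome {genome.genome_id}")
    members = sorted(exclusive_gene_ids, key=lambda g: idx[g])
    regions: list[tuple[int, int, list[str]]] = []
    cur: list[str] = []
    for g in members:
        if cur and idx[g] - idx[cur[-1]] - 1 > max_gene_gap:
            regions.append(_close_region(cur, order, idx))
            cur = []
        cur.append(g)
    if cur:
        regions.append(_close_region(cur, order, idx))
    return regions


def _close_region(members, order, idx):
    first, last = order[idx[members[0]]], order[idx[members[-1]]]
    return (first.start, last.end, list(members))


def transporter_breadth(table: AnnotationTable,
                        category_members: set[str]
                        ) -> tuple[int, int]:
    """(protein count, distinct KO count) of proteins whose KO annotation
    falls in the supplied category (e.g. a KEGG Brite transporter set)."""
    if not category_members:
        raise ValueError("category member list must be non-empty")
    n_proteins = 0
    kos: set[str] = set()
    for d in table.values():
        hit = set(d.get("KO", [])) & category_members
        if hit:
            n_proteins += 1
            kos |= hit
    return n_proteins, len(kos)


def count_transposases(table: AnnotationTable,
                       marker_ids: tuple[str, ...] | list[str] | None = None
                       ) -> int:
    """Number of features carrying >= 1 transposase marker id (each feature
    counts once regardless of how many markers it carries).  Default marker
    vocabulary is the KO+COG set; pass ``TRANSPOSASE_PFAM`` for surveys."""
    markers = set(marker_ids if marker_ids is not None
                  else TRANSPOSASE_KO + TRANSPOSASE_COG)
    if not markers:
        raise ValueError("marker id list must be non-empty")
    n = 0
    for d in table.values():
        ids = set(d.get("KO", [])) | set(d.get("COG", [])) | set(d.get("Pfam", []))
        if ids & markers:
            n += 1
    return n


# ---------------------------------------------------------------------------
# Welch one-sided t-test (from the formula)


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    mean_x: float
    mean_y: float
    n_x: int
    n_y: int


def welch_one_sided(x_values, y_values, alternative: str = "greater"
                    ) -> WelchResult:
    """One-sided Welch two-sample t-test.

    ``t = (x̄ − ȳ) / sqrt(s²x/nx + s²y/ny)`` with sample variances
    (n−1 denominators); degrees of freedom by Welch–Satterthwaite; p is the
    tail probability of Student's t (upper tail for ``greater``)."""
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            # degenerate but symmetric: no evidence either way
            return WelchResult(0.0, float(len(x) + len(y) - 2), 0.5,
                               float(x.mean()), float(y.mean()),
                               len(x), len(y))
        raise ValueError("both groups have zero variance with unequal means; "
                         "the t statistic is undefined")
    se2 = vx / len(x) + vy / len(y)
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((vx / len(x)) ** 2 / (len(x) - 1)
                     + (vy / len(y)) ** 2 / (len(y) - 1))
    if alternative == "greater":
        p = float(stats.t.sf(t, df))
    elif alternative == "less":
        p = float(stats.t.cdf(t, df))
    else:
        raise ValueError("alternative must be 'greater' or 'less'")
    return WelchResult(float(t), float(df), p, float(x.mean()),
                       float(y.mean()), len(x), len(y))


def crispr_transposase_test(survey: pd.DataFrame) -> WelchResult:
    """Welch one-sided test that genomes with an annotated CRISPR carry more
    transposases.

    ``survey`` needs columns ``crispr_present`` (boolean-like) and
    ``transposase_count``; each stratum must have >= 2 rows."""
    for col in ("crispr_present", "transposase_count"):
        if col not in survey.columns:
            raise ValueError(f"survey table missing column {col!r}")
    flags = survey["crispr_present"].astype(bool)
    with_crispr = survey.loc[flags, "transposase_count"].to_numpy(float)
    without = survey.loc[~flags, "transposase_count"].to_numpy(float)
    if len(with_crispr) < 2 or len(without) < 2:
        raise ValueError("each CRISPR stratum needs >= 2 genomes")
    return welch_one_sided(with_crispr, without, alternative="greater")


def read_survey(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"genome_id", "crispr_present", "transposase_count"} \
        - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    if (df["transposase_count"] < 0).any():
        raise ValueError("transposase counts must be >= 0")
    return df
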