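"""Readers and writers for every external format the pipeline touches.

Coordinate convention: all external formats (GFF3, region/island CSVs,
tabular hits) are 1-based inclusive; everything in memory is 0-based
half-open.  :func:`to_internal` / :func:`to_external` perform the conversion
and are involutions of each other.  Readers never silently drop records:
skipped lines are reported through the module logger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import AnnotatedGenome, Feature

logger = logging.getLogger("straindiff.io")

_NT_ALPHABET = set("ACGTRYKMBVDHSWN")
_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")


def to_internal(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def to_external(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, uppercased sequence) pairs.

    Raises ``ValueError`` (with a line number) on malformed headers or
    characters outside the nucleotide/protein alphabets.  An empty file
    yields an empty list with a logged warning.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is not None:
            records.append((header, "".join(chunks).upper()))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise ValueError(f"{path}:{lineno}: empty FASTA header")
                chunks = []
            else:
                if header is None:
                    raise ValueError(
                        f"{path}:{lineno}: sequence data before any '>' header")
                bad = set(line.upper()) - _NT_ALPHABET - _AA_ALPHABET
                if bad:
                    raise ValueError(
                        f"{path}:{lineno}: non-alphabet characters {sorted(bad)}")
                chunks.append(line)
    flush()
    if not records:
        logger.warning("FASTA file %s contains no records", path)
    return records


def write_fasta(records, path, wrap: int = 60) -> None:
    records = list(records)
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    seq_records = [SeqRecord(Seq(seq), id=str(rid), description="")
                   for rid, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# GFF3

_GFF_KIND = {"CDS": "CDS", "rRNA": "rRNA", "tRNA": "tRNA", "tmRNA": "tmRNA",
             "CRISPR": "CRISPR", "repeat_region": "CRISPR"}


def read_gff3(path, genome_id: str, sequence: str) -> AnnotatedGenome:
    """Parse a GFF3 file into an :class:`AnnotatedGenome`.

    KO/COG/Pfam tags are taken from ``Dbxref`` entries (``KO:K00001`` style)
    or from direct ``KO=``/``COG=``/``Pfam=`` attribute keys.  Features whose
    coordinates exceed the sequence length raise a ``ValueError`` naming the
    feature.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    features: list[Feature] = []
    n = len(sequence)
    for rec in db.all_features():
        kind = _GFF_KIND.get(rec.featuretype)
        if kind is None:
            logger.info("skipping %s feature at %s:%s (unhandled type)",
                        rec.featuretype, rec.start, rec.end)
            continue
        fid = rec.attributes.get("ID", [f"{rec.featuretype}_{rec.start}"])[0]
        start, end = to_internal(rec.start, rec.end)
        if end > n:
            raise ValueError(
                f"feature {fid} ends at {rec.end}, beyond sequence length {n}")
        ko, cog, pfam = [], [], []
        for ref in rec.attributes.get("Dbxref", []):
            if ":" in ref:
                vocab, val = ref.split(":", 1)
                {"KO": ko, "COG": cog, "Pfam": pfam,
                 "PFAM": pfam}.get(vocab, []).append(val)
        ko += rec.attributes.get("KO", [])
        cog += rec.attributes.get("COG", [])
        pfam += rec.attributes.get("Pfam", [])
        features.append(Feature(
            feature_id=fid, kind=kind, start=start, end=end,
            strand=rec.strand if rec.strand in "+-" else "+",
            product=rec.attributes.get("product", [""])[0],
            ko=ko, cog=cog, pfam=pfam,
        ))
    return AnnotatedGenome(genome_id, sequence, features)


def write_gff3(genome: AnnotatedGenome, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.genome_id} 1 {len(genome)}\n")
        for f in genome.features:
            start, end = to_external(f.start, f.end)
            attrs = [f"ID={f.feature_id}"]
            if f.product:
                attrs.append(f"product={f.product}")
            dbxref = ([f"KO:{k}" for k in f.ko] + [f"COG:{c}" for c in f.cog]
                      + [f"Pfam:{p}" for p in f.pfam])
            if dbxref:
                attrs.append("Dbxref=" + ",".join(dbxref))
            fh.write("\t".join([
                genome.genome_id, "straindiff", f.kind, str(start), str(end),
                ".", f.strand, ".", ";".join(attrs)]) + "\n")


def read_genome(fasta_path, gff3_path, protein_fasta=None,
                annotation_table=None) -> AnnotatedGenome:
    """Convenience loader: nucleotide FASTA + GFF3 (+ protein FASTA
    + annotation table) -> fully populated AnnotatedGenome."""
    records = read_fasta(fasta_path)
    if len(records) != 1:
        raise ValueError(f"{fasta_path}: expected exactly one sequence, "
                         f"found {len(records)}")
    gid, seq = records[0]
    genome = read_gff3(gff3_path, gid, seq)
    if protein_fasta is not None:
        prots = dict(read_fasta(protein_fasta))
        for f in genome.features:
            if f.kind == "CDS" and f.feature_id in prots:
                f.protein = prots[f.feature_id]
    if annotation_table is not None:
        tags = read_annotation_table(annotation_table)
        for f in genome.features:
            if f.feature_id in tags:
                t = tags[f.feature_id]
                f.ko = f.ko or t.get("KO", [])
                f.cog = f.cog or t.get("COG", [])
                f.pfam = f.pfam or t.get("Pfam", [])
    return genome


# ---------------------------------------------------------------------------
# alignment blocks (XMFA / Mauve backbone dialect)


@dataclass
class RawBlock:
    """One imported homology block.  Either interval may be ``None``
    (sequence absent from that genome); internal 0-based half-open."""

    a_interval: tuple[int, int] | None
    b_interval: tuple[int, int] | None
    strand: str = "+"
    identity: float | None = None


def read_alignment_blocks(path, dialect: str = "backbone") -> list[RawBlock]:
    if dialect == "xmfa":
        return _read_xmfa(path)
    if dialect == "backbone":
        return _read_backbone(path)
    raise ValueError(f"unknown alignment dialect {dialect!r}")


def _read_xmfa(path) -> list[RawBlock]:
    blocks: list[RawBlock] = []
    for aln in AlignIO.parse(str(path), "mauve"):
        recs = [r for r in aln if len(str(r.seq).replace("-", "")) > 0]
        if len(aln) > 2:
            raise ValueError(f"{path}: XMFA with {len(aln)} genomes; only "
                             "pairwise input is supported")
        ivs: dict[int, tuple[tuple[int, int], int]] = {}
        for rec in recs:
            idx = 0 if rec.id.split("/")[0].endswith("1") or len(recs) == 1 else 1
            # Biopython's mauve parser puts 0-based start/end in annotations
            ivs[idx] = ((rec.annotations["start"], rec.annotations["end"]),
                        rec.annotations.get("strand", 1))
        if len(recs) == 2:
            # order records by their sequence index in the file
            first, second = recs
            iv1 = (first.annotations["start"], first.annotations["end"])
            iv2 = (second.annotations["start"], second.annotations["end"])
            strand = "+" if first.annotations.get("strand", 1) == \
                second.annotations.get("strand", 1) else "-"
            ident = _column_identity(str(first.seq), str(second.seq))
            blocks.append(RawBlock(iv1, iv2, strand, ident))
        elif len(recs) == 1:
            rec = recs[0]
            iv = (rec.annotations["start"], rec.annotations["end"])
            which = rec.id
            if which.startswith("1") or "A" in which:
                blocks.append(RawBlock(iv, None))
            else:
                blocks.append(RawBlock(None, iv))
    return blocks


def _column_identity(row_a: str, row_b: str) -> float:
    cols = matches = 0
    for x, y in zip(row_a, row_b):
        cols += 1
        if x == y and x != "-":
            matches += 1
    return matches / cols if cols else 0.0


def _read_backbone(path) -> list[RawBlock]:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 4:
        raise ValueError(
            f"{path}: backbone table has {df.shape[1]} columns; pairwise "
            "input (4 columns: two genomes x start/end) is required")
    blocks: list[RawBlock] = []
    for _, row in df.iterrows():
        vals = [int(v) for v in row]
        a_raw = vals[0], vals[1]
        b_raw = vals[2], vals[3]

        def conv(lo: int, hi: int) -> tuple[tuple[int, int] | None, bool]:
            if lo == 0 and hi == 0:
                return None, False
            rev = lo < 0
            lo, hi = abs(lo), abs(hi)
            if lo > hi:
                lo, hi = hi, lo
            return to_internal(lo, hi), rev

        a_iv, a_rev = conv(*a_raw)
        b_iv, b_rev = conv(*b_raw)
        strand = "-" if (a_rev != b_rev) else "+"
        blocks.append(RawBlock(a_iv, b_iv, strand))
    return blocks


# ---------------------------------------------------------------------------
# tabular protein hits (12-column alignment dialect)

HIT_COLUMNS = ["query_id", "subject_id", "percent_identity", "alignment_length",
               "mismatches", "gap_opens", "q_start", "q_end", "s_start",
               "s_end", "e_value", "bit_score"]


@dataclass
class TabularHit:
    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if not 0 <= self.percent_identity <= 100:
            raise ValueError(f"{self.query_id}->{self.subject_id}: "
                             f"percent_identity {self.percent_identity} out of range")
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")


def read_tabular_hits(path) -> list[TabularHit]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] != 12:
        raise ValueError(f"{path}: expected 12 tab-separated columns, "
                         f"found {df.shape[1]}")
    df.columns = HIT_COLUMNS
    return [TabularHit(
        str(r.query_id), str(r.subject_id), float(r.percent_identity),
        int(r.alignment_length), int(r.mismatches), int(r.gap_opens),
        int(r.q_start), int(r.q_end), int(r.s_start), int(r.s_end),
        float(r.e_value), float(r.bit_score)) for r in df.itertuples()]


# ---------------------------------------------------------------------------
# annotation tables, islands, regions


def read_annotation_table(path) -> dict[str, dict[str, list[str]]]:
    """Headered CSV: feature_id, ko, cog, pfam, product; list columns are
    semicolon-separated."""
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"feature_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")

    def split(v: str) -> list[str]:
        return [t for t in str(v).split(";") if t]

    out: dict[str, dict[str, list[str]]] = {}
    for r in df.itertuples():
        out[r.feature_id] = {
            "KO": split(getattr(r, "ko", "")),
            "COG": split(getattr(r, "cog", "")),
            "Pfam": split(getattr(r, "pfam", "")),
            "product": getattr(r, "product", ""),
        }
    return out


def write_annotation_table(genome: AnnotatedGenome, path) -> None:
    rows = [{"feature_id": f.feature_id, "ko": ";".join(f.ko),
             "cog": ";".join(f.cog), "pfam": ";".join(f.pfam),
             "product": f.product} for f in genome.features]
    pd.DataFrame(rows, columns=["feature_id", "ko", "cog", "pfam", "product"]
                 ).to_csv(path, index=False)


def read_island_coords(path) -> list[tuple[int, int]]:
    """Island CSV with 1-based inclusive start/end columns -> internal
    0-based half-open intervals."""
    df = pd.read_csv(path)
    missing = {"start", "end"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    out = []
    for r in df.itertuples():
        out.append(to_internal(int(r.start), int(r.end)))
    return out


REGION_COLUMNS = ["region_id", "class", "genome", "start", "end",
                  "partner_start", "partner_end", "n_features", "feature_ids"]


def write_regions_csv(regions, path) -> None:
    """Write RegionCall objects (see :mod:`straindiff.regions`) as the
    region table CSV; coordinates 1-based inclusive."""
    rows = []
    for r in regions:
        for genome_label, iv, piv, fids in (
                ("A", r.a_interval, r.b_interval, r.feature_ids_a),
                ("B", r.b_interval, r.a_interval, r.feature_ids_b)):
            if iv is None:
                continue
            s, e = to_external(*iv)
            ps, pe = to_external(*piv) if piv else ("", "")
            rows.append({
                "region_id": r.region_id, "class": r.region_class,
                "genome": genome_label, "start": s, "end": e,
                "partner_start": ps, "partner_end": pe,
                "n_features": len(fids), "feature_ids": ";".join(fids)})
    pd.DataFrame(rows, columns=REGION_COLUMNS).to_csv(path, index=False)


def read_regions_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(REGION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    return df
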