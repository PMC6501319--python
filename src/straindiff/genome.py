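"""Core in-memory containers shared by every pipeline stage.

An :class:`AnnotatedGenome` bundles one nucleotide sequence with its ordered
feature list; a :class:`Feature` is one annotated element (CDS, rRNA, ...)
with functional tags.  External file formats use 1-based inclusive
coordinates; everything in memory is 0-based half-open.  The conversion is
performed exactly once, in the readers/writers of :mod:`straindiff.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


FEATURE_KINDS = ("CDS", "rRNA", "tRNA", "tmRNA", "CRISPR", "other")


@dataclass
class Feature:
    """One annotated genomic element.

    ``start``/``end`` are 0-based half-open on the forward axis regardless of
    strand.  ``protein`` is the already-translated product for CDS features
    (no stop symbol); it is never re-derived from the nucleotide sequence on
    read.
    """

    feature_id: str
    kind: str
    start: int
    end: int
    strand: str = "+"
    product: str = ""
    ko: list[str] = field(default_factory=list)
    cog: list[str] = field(default_factory=list)
    pfam: list[str] = field(default_factory=list)
    protein: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            self.kind = "other"
        if self.start > self.end:
            raise ValueError(
                f"feature {self.feature_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.feature_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def shifted(self, offset: int) -> "Feature":
        return replace(self, start=self.start + offset, end=self.end + offset)

    def tags(self, vocabulary: str) -> list[str]:
        """Tag list for one vocabulary: ``"KO"``, ``"COG"`` or ``"Pfam"``."""
        key = vocabulary.lower()
        if key == "ko":
            return self.ko
        if key == "cog":
            return self.cog
        if key == "pfam":
            return self.pfam
        raise KeyError(f"unknown annotation vocabulary {vocabulary!r}")


@dataclass
class AnnotatedGenome:
    """A genome sequence plus its sorted feature annotations."""

    genome_id: str
    sequence: str
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.features.sort(key=lambda f: (f.start, f.end))
        n = len(self.sequence)
        for f in self.features:
            if f.end > n:
                raise ValueError(
                    f"feature {f.feature_id} ends at {f.end}, beyond sequence "
                    f"length {n} of {self.genome_id}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def cds(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "CDS"]

    def feature_by_id(self, feature_id: str) -> Feature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(f"no feature {feature_id!r} in genome {self.genome_id}")

    def features_within(self, start: int, end: int) -> list[Feature]:
        """Features fully contained in [start, end) (0-based half-open)."""
        return [f for f in self.features if f.start >= start and f.end <= end]

    def features_overlapping(self, start: int, end: int) -> list[Feature]:
        return [f for f in self.features if f.start < end and f.end > start]

    def proteome(self) -> dict[str, str]:
        """feature_id -> protein sequence for all CDS with a translation."""
        return {f.feature_id: f.protein for f in self.cds if f.protein}


_COMPLEMENT = str.maketrans("ACGTRYKMBVDHN", "TGCAYRMKVBHDN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
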