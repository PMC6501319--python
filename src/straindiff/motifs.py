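"""[NiFe]-hydrogenase group classification by wildcard sequence motifs.

[NiFe]-hydrogenases are classified into functional groups (1b respiratory,
1d membrane-anchored periplasmic, 2b sensory, ...) by conserved large-subunit
motifs (L1–L4, around the Ni-binding cysteines) and small-subunit FeS-cluster
binding motifs (proximal / medial / distal).  Patterns are strings over the
amino-acid alphabet where ``x`` (or ``X``) is a wildcard; a motif is
"compatible" with a group when its best window deviates from the pattern at
no more than ``max_mismatch`` non-wildcard positions (single-residue
deviations are conventionally tolerated but always reported).  The
twin-arginine (Tat) export signal RRxFxK is searched near the N-terminus of
the small subunit.

The shipped pattern database (``data/hydrogenase_patterns.tsv``) contains
only motifs with a stated provenance; further group patterns (e.g. the full
1b L1–L4 set) must be supplied by the user from a published classification
scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

WILDCARD = "x"
TAT_PATTERN = "RRxFxK"


@dataclass(frozen=True)
class MotifPattern:
    name: str  # L1 | L2 | L3 | L4 | proximal[_i] | medial | distal | tat
    group: str  # e.g. 1b, 1d, 1f, 2b
    pattern: str  # amino-acid letters + wildcard x/X
    subunit: str = "large"  # large | small
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        for ch in self.pattern:
            if not (ch.isalpha()):
                raise ValueError(f"bad pattern character {ch!r} in {self.name}")

    def letters(self) -> str:
        """Pattern with wildcards normalised to lowercase 'x'."""
        return "".join(WILDCARD if c in "xX" else c.upper()
                       for c in self.pattern)


@dataclass
class MotifHit:
    pattern_name: str
    start: int  # 1-based window start in the protein
    mismatch_positions: list[int]  # 1-based within the pattern, non-wildcard only
    deviations: list[str] = field(default_factory=list)

    @property
    def n_mismatch(self) -> int:
        return len(self.mismatch_positions)


def match_at(window: str, pattern: str) -> list[int]:
    """Mismatch positions (1-based) of a window against an equal-length
    wildcard pattern; wildcard positions never mismatch."""
    if len(window) != len(pattern):
        raise ValueError(
            f"window length {len(window)} != pattern length {len(pattern)}")
    out = []
    for i, (w, p) in enumerate(zip(window.upper(), pattern), start=1):
        if p in "xX":
            continue
        if w != p.upper():
            out.append(i)
    return out


def scan(protein: str, pattern: str) -> MotifHit:
    """Best-matching window of the pattern in the protein: minimal mismatch
    count, ties broken by leftmost start."""
    m = len(pattern)
    if len(protein) < m:
        raise ValueError(f"protein ({len(protein)} aa) shorter than pattern "
                         f"({m} aa)")
    best_pos, best_mis = 0, None
    for i in range(len(protein) - m + 1):
        mis = match_at(protein[i:i + m], pattern)
        if best_mis is None or len(mis) < len(best_mis):
            best_pos, best_mis = i, mis
            if not mis:
                break
    window = protein[best_pos:best_pos + m]
    deviations = [
        f"{window[p - 1].upper()} instead of {pattern[p - 1].upper()} "
        f"at position {p}" for p in best_mis]
    return MotifHit(pattern_name="", start=best_pos + 1,
                    mismatch_positions=best_mis, deviations=deviations)


def detect_tat(protein: str, window_len: int = 50) -> MotifHit | None:
    """First occurrence of the twin-arginine motif RRxFxK within the
    N-terminal ``window_len`` residues, or ``None``."""
    if not protein:
        raise ValueError("empty protein")
    m = len(TAT_PATTERN)
    limit = min(len(protein), window_len)
    for i in range(limit - m + 1):
        mis = match_at(protein[i:i + m], TAT_PATTERN)
        if not mis:
            return MotifHit("tat", i + 1, [])
    return None


# ---------------------------------------------------------------------------
# pattern database


def load_pattern_db(path=None) -> list[MotifPattern]:
    """Load a tab-separated pattern database (columns: group, motif_name,
    pattern, subunit, provenance).  Defaults to the shipped file."""
    if path is None:
        source = resources.files("straindiff.data") / "hydrogenase_patterns.tsv"
        df = pd.read_csv(str(source), sep="\t", comment="#")
    else:
        df = pd.read_csv(Path(path), sep="\t", comment="#")
    required = {"group", "motif_name", "pattern", "subunit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pattern database missing column(s) {sorted(missing)}")
    return [MotifPattern(r.motif_name, str(r.group), r.pattern, r.subunit,
                         getattr(r, "provenance", ""))
            for r in df.itertuples()]


@dataclass
class MotifVerdict:
    group: str
    motif: MotifPattern
    hit: MotifHit
    compatible: bool


@dataclass
class GroupReport:
    verdicts: list[MotifVerdict]
    compatible_groups: list[str]
    tat: MotifHit | None
    rationale: list[str]

    def for_group(self, group: str) -> list[MotifVerdict]:
        return [v for v in self.verdicts if v.group == group]


def classify(large_subunit: str, small_subunit: str,
             pattern_db: list[MotifPattern] | None = None,
             max_mismatch: int = 1) -> GroupReport:
    """Scan every group's motifs against the two subunits and call the
    group(s) whose motifs are all compatible (best-window mismatches
    <= ``max_mismatch``).  Deviations are reported as
    "observed instead of expected at position p" strings; the Tat verdict is
    attached for the small subunit.  Classification is deterministic and
    independent of pattern file ordering."""
    if pattern_db is None:
        pattern_db = load_pattern_db()
    if not pattern_db:
        raise ValueError("empty pattern database")

    verdicts: list[MotifVerdict] = []
    rationale: list[str] = []
    groups = sorted({p.group for p in pattern_db if p.name != "tat"})
    for group in groups:
        for motif in sorted((p for p in pattern_db if p.group == group
                             and p.name != "tat"),
                            key=lambda p: (p.name, p.pattern)):
            target = large_subunit if motif.subunit == "large" else small_subunit
            pat = motif.letters()
            if len(target) < len(pat):
                continue
            hit = scan(target, pat)
            hit.pattern_name = motif.name
            ok = hit.n_mismatch <= max_mismatch
            verdicts.append(MotifVerdict(group, motif, hit, ok))
            if hit.deviations:
                rationale.append(
                    f"group {group} {motif.name}: " + "; ".join(hit.deviations))

    compatible = []
    for group in groups:
        gv = [v for v in verdicts if v.group == group]
        if gv and all(v.compatible for v in gv):
            compatible.append(group)
            rationale.append(
                f"group {group}: all {len(gv)} motifs compatible "
                f"(max_mismatch={max_mismatch})")
    if not compatible:
        near = sorted(verdicts, key=lambda v: v.hit.n_mismatch)[:3]
        for v in near:
            rationale.append(
                f"near miss: group {v.group} {v.motif.name} with "
                f"{v.hit.n_mismatch} mismatches")

    tat = detect_tat(small_subunit) if small_subunit else None
    if tat:
        rationale.append(f"Tat motif {TAT_PATTERN} present in the small "
                         f"subunit at position {tat.start}")
    return GroupReport(verdicts, compatible, tat, rationale)


def report_to_dataframe(report: GroupReport) -> pd.DataFrame:
    return pd.DataFrame([{
        "group": v.group, "motif": v.motif.name, "subunit": v.motif.subunit,
        "pattern": v.motif.pattern, "window_start": v.hit.start,
        "n_mismatch": v.hit.n_mismatch,
        "deviations": "; ".join(v.hit.deviations),
        "compatible": v.compatible,
    } for v in report.verdicts])
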