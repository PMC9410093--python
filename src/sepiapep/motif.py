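"""Degenerate-motif scanning, global alignment and family classification.

Orcokinin-family neuropeptides share a glycine-rich GGG core; the
orcokinin-B branch additionally carries the hexapeptide DS(L/I)GGG that the
cuttlefish FLGamide/So-orcokinin-B peptides preserve.  Classification is a
rule cascade over degenerate motif hits, with a consensus-alignment
fallback for the FCAN (feeding circuit activating neuropeptide) family,
whose name was historically misapplied to cephalopod orcokinin-B homologs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class MotifPattern:
    """An ordered list of residue classes; each element is a set of allowed
    residues (singleton = fixed position, full alphabet = wildcard)."""

    name: str
    elements: tuple[frozenset, ...]

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("empty pattern")
        for el in self.elements:
            if not el or set(el) - set(ALPHABET):
                raise ValueError(f"bad residue class {el!r}")

    def __len__(self) -> int:
        return len(self.elements)

    def to_tokens(self) -> str:
        parts = []
        for el in self.elements:
            if len(el) == len(ALPHABET):
                parts.append(".")
            elif len(el) == 1:
                parts.append(next(iter(el)))
            else:
                parts.append("(" + "/".join(sorted(el)) + ")")
        return " ".join(parts)


def parse_pattern(name: str, tokens: Sequence[str]) -> MotifPattern:
    """Build a pattern from tokens: a residue, ``(X/Y)``, or ``.``."""
    elements = []
    for tok in tokens:
        if tok == ".":
            elements.append(frozenset(ALPHABET))
        elif tok.startswith("(") and tok.endswith(")"):
            elements.append(frozenset(tok[1:-1].split("/")))
        else:
            elements.append(frozenset(tok))
    return MotifPattern(name=name, elements=tuple(elements))


def load_patterns(path=None) -> dict[str, MotifPattern]:
    """Load the pattern library (one line per pattern: name then tokens).

    Without ``path``, the packaged library is used.
    """
    if path is None:
        text = resources.files("sepiapep").joinpath("data/patterns.txt").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    patterns = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, *tokens = line.split()
        patterns[name] = parse_pattern(name, tokens)
    return patterns


def scan_motif(sequence: str, pattern: MotifPattern) -> list[int]:
    """All 1-based positions where the pattern matches; overlaps reported."""
    k = len(pattern)
    hits = []
    for i in range(len(sequence) - k + 1):
        if all(sequence[i + j] in pattern.elements[j] for j in range(k)):
            hits.append(i + 1)
    return hits


# ---------------------------------------------------------------------------
# Alignment


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity_fraction: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("unequal aligned lengths")


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def global_align(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> AlignmentResult:
    """Optimal global alignment with affine gaps (gap of length L costs
    ``gap_open + (L-1) * gap_extend``); deterministic first-optimal traceback.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alignment = next(iter(aligner.align(a, b)))
    ga, gb = alignment[0], alignment[1]
    ident = sum(x == y and x != "-" for x, y in zip(ga, gb)) / len(ga)
    return AlignmentResult(ga, gb, float(alignment.score), ident)


# ---------------------------------------------------------------------------
# Consensus


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _conservative_pair(x: str, y: str) -> bool:
    """True when two residues are a conservative substitution (positive
    BLOSUM62 score), e.g. L/I or S/T but not A/C."""
    return _BLOSUM62[x, y] > 0


def build_consensus(
    sequences: Sequence[str], majority: float = 0.8, name: str = "consensus"
) -> MotifPattern:
    """Column-wise consensus of an aligned block.

    Per column: a fixed residue when its frequency reaches ``majority``; a
    two-residue class when the top two residues jointly reach it AND form a
    conservative pair; otherwise a wildcard.  All-gap columns are dropped.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    width = len(sequences[0])
    if any(len(s) != width for s in sequences):
        raise ValueError("sequences must be aligned to equal length")
    elements = []
    n = len(sequences)
    for col in range(width):
        counts: dict[str, int] = {}
        for s in sequences:
            c = s[col]
            if c != "-":
                counts[c] = counts.get(c, 0) + 1
        if not counts:
            continue  # all-gap column
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        top, top_n = ranked[0]
        if top_n / n >= majority:
            elements.append(frozenset(top))
        elif (
            len(ranked) >= 2
            and (top_n + ranked[1][1]) / n >= majority
            and _conservative_pair(top, ranked[1][0])
        ):
            elements.append(frozenset({top, ranked[1][0]}))
        else:
            elements.append(frozenset(ALPHABET))
    return MotifPattern(name=name, elements=tuple(elements))


def progressive_align(sequences: Sequence[str], **align_kw) -> list[str]:
    """Progressive multiple alignment anchored on the first sequence.

    Each sequence is pairwise-aligned to the first; gaps opened in the
    anchor are propagated.  Adequate for short, near-identical peptide
    blocks; not a general MSA.
    """
    if len(sequences) < 2:
        return list(sequences)
    rows = [sequences[0]]
    for seq in sequences[1:]:
        res = global_align(rows[0].replace("-", ""), seq, **align_kw)
        rows = _merge(rows, res)
    return rows


def _merge(rows: list[str], res: AlignmentResult) -> list[str]:
    """Insert the anchor gaps of ``res`` into all existing rows, append the
    new gapped sequence."""
    anchor_old = rows[0]
    out = [""] * len(rows)
    new = ""
    j = 0  # index into existing gapped rows
    for ca, cb in zip(res.aligned_a, res.aligned_b):
        if ca == "-":
            for r in range(len(rows)):
                out[r] += "-"
            new += cb
        else:
            while j < len(anchor_old) and anchor_old[j] == "-":
                for r in range(len(rows)):
                    out[r] += rows[r][j]
                new += "-"
                j += 1
            for r in range(len(rows)):
                out[r] += rows[r][j]
            new += cb
            j += 1
    while j < len(anchor_old):
        for r in range(len(rows)):
            out[r] += rows[r][j]
        new += "-"
        j += 1
    return out + [new]


# ---------------------------------------------------------------------------
# Family classification


@dataclass(frozen=True)
class FamilyCall:
    family: str  # orcokinin_B | orcokinin_C | FCAN | unclassified
    evidence: tuple[str, ...] = ()


def classify_family(
    sequence: str,
    patterns: Optional[dict[str, MotifPattern]] = None,
    fcan_consensus: Optional[str] = None,
    fcan_identity_threshold: float = 0.5,
) -> FamilyCall:
    """Rule cascade over the pattern library.

    orcokinin_B requires a hit of the DS(L/I)GGG-class core (the packaged
    library carries the strict hexapeptide and the D(S/T)(L/I)GGG family
    class); orcokinin_C requires the GGG core with orcokinin-C flanking
    classes but no DS(L/I)-class hit; FCAN requires consensus alignment
    identity above threshold and no orcokinin motif; otherwise unclassified.
    """
    patterns = patterns if patterns is not None else load_patterns()
    if fcan_consensus is None and "FCAN_consensus" in patterns:
        els = patterns["FCAN_consensus"].elements
        if all(len(el) == 1 for el in els):
            fcan_consensus = "".join(next(iter(el)) for el in els)
    evidence = []

    b_hits = []
    for key in ("orcokinin_B_core", "flgamide_hexapeptide"):
        if key in patterns:
            for pos in scan_motif(sequence, patterns[key]):
                b_hits.append(f"{key}@{pos}")
    if b_hits:
        return FamilyCall("orcokinin_B", tuple(b_hits))

    if "orcokinin_C_core" in patterns:
        c_hits = scan_motif(sequence, patterns["orcokinin_C_core"])
        if c_hits:
            return FamilyCall(
                "orcokinin_C", tuple(f"orcokinin_C_core@{p}" for p in c_hits)
            )

    if fcan_consensus:
        res = global_align(sequence, fcan_consensus)
        evidence.append(f"fcan_identity={res.identity_fraction:.3f}")
        if res.identity_fraction >= fcan_identity_threshold:
            return FamilyCall("FCAN", tuple(evidence))

    return FamilyCall("unclassified", tuple(evidence))
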