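"""Prohormone parsing and mature-peptide excision.

Neuropeptide precursors are processed by signal peptidase (removal of the
N-terminal signal peptide), prohormone convertases (endoproteolysis at runs
of basic residues, Lys/Arg) and carboxypeptidase E (trimming of the exposed
basic residues).  A C-terminal glycine left on a liberated peptide is
converted by PAM into a C-terminal amide; an N-terminal glutamine may
cyclize to pyroglutamate.  This module implements that canonical processing
model: peptides are the maximal segments strictly between basic runs, with
flanking basic residues removed.

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

# Kyte-Doolittle hydropathy, used by the signal-peptide heuristic.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


class PrecursorError(ValueError):
    """Raised for malformed or out-of-contract precursor input."""


@dataclass(frozen=True)
class Precursor:
    """An annotated prohormone sequence.

    ``signal_end`` is the 1-based index of the last residue of the signal
    peptide, when known.  ``is_partial`` marks N- or C-terminally incomplete
    sequences recovered from fragmentary transcripts.
    """

    id: str
    sequence: str
    signal_end: Optional[int] = None
    is_partial: bool = False

    def __post_init__(self) -> None:
        seq = self.sequence
        if seq.endswith("*"):  # stop-codon mark, stripped at parse time
            seq = seq[:-1]
            object.__setattr__(self, "sequence", seq)
        if not seq:
            raise PrecursorError(f"{self.id}: empty sequence")
        bad = set(seq) - STANDARD_AA
        if bad:
            raise PrecursorError(f"{self.id}: non-standard residues {sorted(bad)}")
        if self.signal_end is not None and not (1 <= self.signal_end < len(seq)):
            raise PrecursorError(f"{self.id}: signal_end {self.signal_end} out of range")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CleavageSite:
    """A mono-/di-/tribasic convertase site: a run of K/R residues."""

    start: int
    end: int
    residues: str

    def __post_init__(self) -> None:
        n = self.end - self.start + 1
        if n not in (1, 2, 3) or n != len(self.residues):
            raise ValueError(f"invalid basic run {self.start}-{self.end} ({self.residues})")
        if set(self.residues) - {"K", "R"}:
            raise ValueError(f"non-basic residues in site: {self.residues}")

    @property
    def kind(self) -> str:
        return {1: "monobasic", 2: "dibasic", 3: "tribasic"}[self.end - self.start + 1]


@dataclass(frozen=True)
class MaturePeptide:
    """A processed peptide: post-PTM sequence plus modification flags.

    ``sequence`` has the amidation-signal glycine already removed when
    ``amidated`` is set.  ``pyroglutamate`` marks an N-terminal Gln that MAY
    cyclize; both forms are retained downstream as variants.  ``copy_index``
    counts identical sequences within one precursor in N→C order.
    """

    sequence: str
    amidated: bool = False
    pyroglutamate: bool = False
    source_precursor: str = ""
    span: tuple[int, int] = (0, 0)
    copy_index: int = 1
    name: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# FASTA I/O


def _parse_tags(description: str) -> dict:
    tags = {}
    for m in re.finditer(r"(\w+)=(\S+)", description):
        tags[m.group(1)] = m.group(2)
    return tags


def read_precursors(path) -> list[Precursor]:
    """Read precursors from FASTA.

    The description line may carry ``signal_end=N`` and ``is_partial=yes|no``
    key-value tags; '*' stop marks are stripped.
    """
    precursors = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tags = _parse_tags(rec.description)
        signal_end = int(tags["signal_end"]) if "signal_end" in tags else None
        is_partial = tags.get("is_partial", "no").lower() in ("yes", "true", "1")
        precursors.append(
            Precursor(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                signal_end=signal_end,
                is_partial=is_partial,
            )
        )
    return precursors


# ---------------------------------------------------------------------------
# Signal peptide


def find_signal_peptide(
    precursor: Precursor,
    window: int = 40,
    core_min: int = 8,
    core_max: int = 15,
    hydropathy_threshold: float = 1.6,
) -> Optional[int]:
    """Locate the likely signal-peptidase cut by a hydrophobicity heuristic.

    Searches the first ``window`` residues for the 8-15 residue core with
    maximal mean Kyte-Doolittle hydropathy; if that mean exceeds the
    threshold, the cut is placed after the first small residue (A/G/S/C)
    following the core.  Returns the 1-based index of the last signal
    residue, or ``None`` when no sufficiently hydrophobic core exists.
    """
    if precursor.is_partial:
        raise PrecursorError(f"{precursor.id}: cannot place a signal peptide on a partial precursor")
    head = precursor.sequence[:window]
    best_mean, best_end = None, None
    for length in range(core_min, core_max + 1):
        for start in range(0, len(head) - length + 1):
            core = head[start : start + length]
            mean = sum(KYTE_DOOLITTLE[a] for a in core) / length
            if best_mean is None or mean > best_mean:
                best_mean, best_end = mean, start + length  # 0-based end-exclusive
    if best_mean is None or best_mean < hydropathy_threshold:
        return None
    for i in range(best_end, min(len(precursor.sequence), window)):
        if precursor.sequence[i] in "AGSC":
            return i + 1  # 1-based index of the small residue
    return best_end  # no small residue downstream: cut at the core end


# ---------------------------------------------------------------------------
# Cleavage sites


def find_cleavage_sites(precursor: Precursor, allow_monobasic: bool = False) -> list[CleavageSite]:
    """Return maximal K/R runs as convertase sites, sorted by start.

    Runs of length 2-3 are di-/tribasic sites; single K/R only count when
    ``allow_monobasic``.  Runs longer than 3 are collapsed to one tribasic
    site anchored at the C-terminal end of the run, so that no zero-length
    peptide is generated.
    """
    sites = []
    for m in re.finditer(r"[KR]+", precursor.sequence):
        start, end = m.start() + 1, m.end()  # 1-based inclusive
        n = end - start + 1
        if n == 1 and not allow_monobasic:
            continue
        if n > 3:
            start = end - 2
        sites.append(CleavageSite(start=start, end=end, residues=precursor.sequence[start - 1 : end]))
    return sites


# ---------------------------------------------------------------------------
# PTM rules and excision


def apply_ptm_rules(raw_segment: str, at_terminus: bool) -> MaturePeptide:
    """Apply amidation and pyroglutamate rules to a raw excised segment.

    A segment ending in G that is followed by a cleavage site (i.e. not at
    the precursor C-terminus) donates that glycine to C-terminal amidation.
    An N-terminal Q flags a possible pyroglutamate variant; the choice
    between the two forms is made downstream during variant enumeration.
    """
    if not raw_segment:
        raise ValueError("empty segment")
    sequence, amidated = raw_segment, False
    if sequence.endswith("G") and not at_terminus:
        sequence, amidated = sequence[:-1], True
    return MaturePeptide(
        sequence=sequence,
        amidated=amidated,
        pyroglutamate=sequence.startswith("Q"),
    )


def excise_peptides(
    precursor: Precursor,
    sites: Optional[Iterable[CleavageSite]] = None,
    min_len: int = 4,
    allow_monobasic: bool = False,
) -> list[MaturePeptide]:
    """Excise mature peptides from a precursor.

    Peptides are the maximal segments strictly between basic runs (signal
    peptide and basic residues excluded), kept when the processed sequence
    has at least ``min_len`` residues.  PTM rules are applied per segment;
    ``copy_index`` is assigned in N→C order among identical sequences.
    """
    if sites is None:
        sites = find_cleavage_sites(precursor, allow_monobasic=allow_monobasic)
    sites = sorted(sites, key=lambda s: s.start)
    for a, b in zip(sites, sites[1:]):
        if b.start <= a.end:
            raise ValueError("overlapping cleavage sites")

    seq = precursor.sequence
    start = (precursor.signal_end or 0) + 1  # first residue after the signal
    boundaries = []  # (seg_start, seg_end, at_terminus)
    pos = start
    for site in sites:
        if site.end < pos:
            continue  # site inside the signal peptide
        boundaries.append((pos, site.start - 1, False))
        pos = site.end + 1
    boundaries.append((pos, len(seq), True))

    peptides = []
    counts: dict[str, int] = {}
    for seg_start, seg_end, at_terminus in boundaries:
        if seg_end < seg_start:
            continue
        raw = seq[seg_start - 1 : seg_end]
        if len(raw) < min_len:  # min_len gates the raw segment, pre-PTM
            continue
        pep = apply_ptm_rules(raw, at_terminus=at_terminus)
        counts[pep.sequence] = counts.get(pep.sequence, 0) + 1
        peptides.append(
            replace(
                pep,
                source_precursor=precursor.id,
                span=(seg_start, seg_end),
                copy_index=counts[pep.sequence],
            )
        )
    return peptides


def count_copies(peptides: Iterable[MaturePeptide]) -> dict[str, int]:
    """Multiset count of peptides by post-PTM sequence."""
    counts: dict[str, int] = {}
    for pep in peptides:
        counts[pep.sequence] = counts.get(pep.sequence, 0) + 1
    return counts


def name_peptides(peptides: list[MaturePeptide], prefix: str = "FLGa") -> list[MaturePeptide]:
    """Assign family names by order of first appearance on the precursor.

    Peptides sharing a sequence share a name; numbering follows N→C order of
    first occurrence, the convention used for FLGa 1..6.
    """
    names: dict[str, str] = {}
    out = []
    for pep in peptides:
        if pep.sequence not in names:
            names[pep.sequence] = f"{prefix} {len(names) + 1}"
        out.append(replace(pep, name=names[pep.sequence]))
    return out


def peptides_to_frame(peptides: Iterable[MaturePeptide]) -> pd.DataFrame:
    rows = [
        {
            "precursor_id": p.source_precursor,
            "name": p.name,
            "start": p.span[0],
            "end": p.span[1],
            "sequence": p.sequence,
            "amidated": p.amidated,
            "pyroglu": p.pyroglutamate,
            "copy_index": p.copy_index,
        }
        for p in peptides
    ]
    return pd.DataFrame(
        rows,
        columns=["precursor_id", "name", "start", "end", "sequence", "amidated", "pyroglu", "copy_index"],
    )


def write_peptides_tsv(peptides: Iterable[MaturePeptide], path) -> None:
    peptides_to_frame(peptides).to_csv(path, sep="\t", index=False)


def read_peptides_tsv(path) -> list[MaturePeptide]:
    df = pd.read_csv(path, sep="\t", dtype={"name": str})
    return [
        MaturePeptide(
            sequence=row.sequence,
            amidated=bool(row.amidated),
            pyroglutamate=bool(row.pyroglu),
            source_precursor=str(row.precursor_id),
            span=(int(row.start), int(row.end)),
            copy_index=int(row.copy_index),
            name="" if pd.isna(row.name_) else str(row.name_),
        )
        for row in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]
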