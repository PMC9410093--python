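"""Peptide mass arithmetic and theoretical fragment-ion series.

Monoisotopic and average residue masses and the modification catalogue are
packaged text resources (``data/residue_masses.tsv``,
``data/modifications.tsv``).  m/z arithmetic uses the proton mass
(1.007276 Da), the MALDI [M+H]+ convention: singly protonated precursor
ions, a/b/y fragment series, charge states up to 2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

from .prohormone import MaturePeptide

PROTON = 1.007276
WATER_MONO = 18.010565
WATER_AVG = 18.0153
CO_MONO = 27.99491


def _load_table(name: str) -> list[list[str]]:
    text = resources.files("sepiapep").joinpath("data").joinpath(name).read_text()
    rows = [line.split("\t") for line in text.strip().splitlines()]
    return rows[1:]  # skip header


RESIDUE_MONO: dict[str, float] = {}
RESIDUE_AVG: dict[str, float] = {}
for _res, _mono, _avg in _load_table("residue_masses.tsv"):
    RESIDUE_MONO[_res] = float(_mono)
    RESIDUE_AVG[_res] = float(_avg)


@dataclass(frozen=True)
class ModificationDelta:
    """A fixed mass shift tied to a terminus or residue type."""

    name: str
    target: str  # 'cterm', 'nterm:Q', or a residue letter
    mono_delta: float
    avg_delta: float


MODIFICATIONS: dict[str, ModificationDelta] = {
    name: ModificationDelta(name, target, float(mono), float(avg))
    for name, target, mono, avg in _load_table("modifications.tsv")
}


@dataclass(frozen=True)
class ModPlacement:
    """A modification applied at a specific site.

    ``site`` is a 1-based residue index, or 0 for a terminal modification.
    """

    mod: ModificationDelta
    site: int = 0


@dataclass(frozen=True)
class FragmentIon:
    series: str  # 'a', 'b' or 'y'
    index: int
    charge: int
    mz: float

    def __post_init__(self) -> None:
        if self.series not in ("a", "b", "y"):
            raise ValueError(f"unknown series {self.series!r}")
        if self.mz <= 0 or self.index < 1 or self.charge < 1:
            raise ValueError("invalid fragment ion")

    @property
    def label(self) -> str:
        sup = "+" * self.charge
        return f"{self.series}{self.index}{sup}"


@dataclass(frozen=True)
class TheoreticalPeptideMass:
    """[M+H]+ bookkeeping for a peptide variant."""

    peptide: MaturePeptide
    variant_sequence: str
    mods: tuple[ModPlacement, ...]
    neutral_mono: float

    @property
    def mh_plus(self) -> float:
        return self.neutral_mono + PROTON


def _residue_masses(sequence: str, kind: str) -> list[float]:
    table = RESIDUE_MONO if kind == "mono" else RESIDUE_AVG
    try:
        return [table[a] for a in sequence]
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None


def peptide_mass(sequence: str, mods: Iterable[ModPlacement] = (), kind: str = "mono") -> float:
    """Neutral peptide mass: residue masses + water + modification deltas."""
    if kind not in ("mono", "avg"):
        raise ValueError("kind must be 'mono' or 'avg'")
    water = WATER_MONO if kind == "mono" else WATER_AVG
    mass = sum(_residue_masses(sequence, kind)) + water
    for pl in mods:
        mass += pl.mod.mono_delta if kind == "mono" else pl.mod.avg_delta
    return mass


def mh_plus(sequence: str, mods: Iterable[ModPlacement] = ()) -> float:
    """Singly protonated monoisotopic m/z."""
    return peptide_mass(sequence, mods) + PROTON


def fragment_ions(
    sequence: str,
    mods: Iterable[ModPlacement] = (),
    series_set: Sequence[str] = ("a", "b", "y"),
    max_charge: int = 1,
) -> list[FragmentIon]:
    """Theoretical a/b/y fragment m/z values.

    b_i is the N-terminal i-residue sum plus a proton, a_i = b_i - CO, and
    y_i is the C-terminal i-residue sum plus water and a proton.  Terminal
    modifications stay with their terminus (C-terminal mods appear only in
    the y series); residue modifications travel with their residue.  The
    full-length b_n/a_n ions are not generated.
    """
    n = len(sequence)
    if n < 2:
        raise ValueError("need at least 2 residues to fragment")
    for s in series_set:
        if s not in ("a", "b", "y"):
            raise ValueError(f"unknown series {s!r}")
    res = _residue_masses(sequence, "mono")
    nterm_extra, cterm_extra = 0.0, 0.0
    for pl in mods:
        if pl.site == 0:
            if pl.mod.target == "cterm":
                cterm_extra += pl.mod.mono_delta
            else:
                nterm_extra += pl.mod.mono_delta
        else:
            res[pl.site - 1] += pl.mod.mono_delta

    ions = []
    prefix = 0.0
    for i in range(1, n):  # b/a ions, indices 1..n-1
        prefix += res[i - 1]
        neutral_b = prefix + nterm_extra
        for z in range(1, max_charge + 1):
            if "b" in series_set:
                ions.append(FragmentIon("b", i, z, (neutral_b + z * PROTON) / z))
            if "a" in series_set:
                ions.append(FragmentIon("a", i, z, (neutral_b - CO_MONO + z * PROTON) / z))
    if "y" in series_set:
        suffix = 0.0
        for i in range(1, n + 1):
            suffix += res[n - i]
            neutral_y = suffix + WATER_MONO + cterm_extra
            for z in range(1, max_charge + 1):
                ions.append(FragmentIon("y", i, z, (neutral_y + z * PROTON) / z))
    return ions


def enumerate_variants(
    peptide: MaturePeptide, alkylated: bool = False
) -> list[TheoreticalPeptideMass]:
    """Expand a mature peptide into its modification variants.

    Amidation is fixed by the peptide's flag.  Pyroglutamate (N-terminal Q)
    is optional; each Met carries 0, 1 or 2 oxygens (none/oxidation/
    dioxidation).  Cys carbamidomethylation is fixed when the sample was
    alkylated with iodoacetamide, otherwise optional per Cys.
    """
    seq = peptide.sequence
    fixed: list[ModPlacement] = []
    if peptide.amidated:
        fixed.append(ModPlacement(MODIFICATIONS["amidation"]))

    choice_sets: list[list[Optional[ModPlacement]]] = []
    if peptide.pyroglutamate and seq.startswith("Q"):
        choice_sets.append([None, ModPlacement(MODIFICATIONS["pyro_glu"])])
    for i, aa in enumerate(seq, start=1):
        if aa == "M":
            choice_sets.append(
                [
                    None,
                    ModPlacement(MODIFICATIONS["oxidation"], i),
                    ModPlacement(MODIFICATIONS["dioxidation"], i),
                ]
            )
        elif aa == "C":
            cam = ModPlacement(MODIFICATIONS["carbamidomethyl"], i)
            if alkylated:
                fixed.append(cam)
            else:
                choice_sets.append([None, cam])

    variants = []
    for combo in itertools.product(*choice_sets):
        mods = tuple(fixed) + tuple(pl for pl in combo if pl is not None)
        variants.append(
            TheoreticalPeptideMass(
                peptide=peptide,
                variant_sequence=seq,
                mods=mods,
                neutral_mono=peptide_mass(seq, mods),
            )
        )
    return variants


def variants_to_frame(variants: Iterable[TheoreticalPeptideMass]):
    """TSV-ready table: sequence, mods, neutral_mono, mh_plus."""
    import pandas as pd

    rows = [
        {
            "name": v.peptide.name,
            "sequence": v.variant_sequence,
            "mods": ";".join(
                f"{pl.mod.name}@{pl.site}" if pl.site else pl.mod.name for pl in v.mods
            ),
            "neutral_mono": round(v.neutral_mono, 5),
            "mh_plus": round(v.mh_plus, 5),
        }
        for v in variants
    ]
    return pd.DataFrame(rows, columns=["name", "sequence", "mods", "neutral_mono", "mh_plus"])
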