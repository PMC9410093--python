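"""Matching theoretical peptides against centroided peak lists.

Emulates a no-enzyme peptidomics search: survey (MS) spectra are matched by
precursor mass at a ppm tolerance (default 200 ppm), fragment (MS/MS)
spectra additionally by their a/b/y ions at an absolute tolerance (default
0.6 Da).  PSMs are scored with a binomial-tail probability: under the null
that peaks fall uniformly over the scanned m/z range, the chance that a
random peak lands inside one fragment window is
``p = n_peaks * 2 * tol_da / mz_range``; the score is -log10 of
P(X >= n_matched) for X ~ Binomial(n_theoretical, p).  This is a simple,
defensible stand-in for a commercial probabilistic search score, not a
reimplementation of one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf
from scipy.stats import binom

from .chem import FragmentIon, TheoreticalPeptideMass, fragment_ions

logger = logging.getLogger(__name__)

DEFAULT_MZ_RANGE = (700.0, 4000.0)  # positive reflector mode survey window


@dataclass
class Spectrum:
    """A centroided peak list with a tissue label.

    ``level`` 1 marks survey (precursor-only) spectra, 2 fragment spectra
    with a selected ``precursor_mz``.  Peaks are (m/z, intensity) pairs kept
    sorted by m/z.
    """

    id: str
    tissue: str
    level: int
    peaks: list[tuple[float, float]]
    precursor_mz: Optional[float] = None

    def __post_init__(self) -> None:
        if self.level not in (1, 2):
            raise ValueError("level must be 1 or 2")
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("negative intensity")
        self.peaks = sorted(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])


@dataclass(frozen=True)
class PeptideSpectrumMatch:
    variant: TheoreticalPeptideMass
    spectrum_id: str
    tissue: str
    n_matched: int
    n_theoretical: int
    ppm_error_precursor: float
    score: float

    def __post_init__(self) -> None:
        if not (0 <= self.n_matched <= max(self.n_theoretical, 1)):
            raise ValueError("matched ion count out of range")


@dataclass
class SearchConfig:
    """Tolerances and thresholds of the search.

    ``score_threshold`` was calibrated on the packaged noise-only simulation
    so that the false-positive rate is at most 1%; see the search
    configuration notes in the documentation.
    """

    tol_ppm: float = 200.0
    tol_da: float = 0.6
    score_threshold: float = 3.0
    series_set: tuple[str, ...] = ("a", "b", "y")
    max_charge: int = 1
    mz_range: tuple[float, float] = DEFAULT_MZ_RANGE

    def __post_init__(self) -> None:
        if self.tol_ppm <= 0 or self.tol_da <= 0:
            raise ValueError("tolerances must be positive")


# ---------------------------------------------------------------------------
# I/O


def read_mgf(path) -> list[Spectrum]:
    """Read spectra from MGF; TITLE may carry ``tissue=...`` and ``level=...``."""
    from .prohormone import _parse_tags

    spectra = []
    with _mgf.read(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry.get("params", {})
            title = str(params.get("title", f"spectrum_{i}"))
            tags = _parse_tags(title)
            level = int(tags.get("level", 2))
            pepmass = params.get("pepmass")
            precursor = float(pepmass[0]) if pepmass else None
            peaks = list(zip(entry["m/z array"].tolist(), entry["intensity array"].tolist()))
            spectra.append(
                Spectrum(
                    id=tags.get("id", title.split()[0] if title.split() else f"spectrum_{i}"),
                    tissue=tags.get("tissue", "unknown"),
                    level=level,
                    peaks=peaks,
                    precursor_mz=precursor,
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path) -> None:
    entries = []
    for s in spectra:
        params = {"title": f"id={s.id} tissue={s.tissue} level={s.level}"}
        if s.precursor_mz is not None:
            params["pepmass"] = s.precursor_mz
        entries.append(
            {
                "m/z array": np.array([m for m, _ in s.peaks]),
                "intensity array": np.array([i for _, i in s.peaks]),
                "params": params,
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def read_peak_list(path, id: str = "", tissue: str = "unknown", level: int = 1) -> Spectrum:
    """Read a plain two-column (m/z, intensity) text peak list."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            peaks.append((float(parts[0]), float(parts[1]) if len(parts) > 1 else 1.0))
    return Spectrum(id=id or str(path), tissue=tissue, level=level, peaks=peaks)


# ---------------------------------------------------------------------------
# Matching


def match_precursor(obs_mz: float, theo_mh: float, tol_ppm: float = 200.0) -> Optional[float]:
    """Signed ppm error when within tolerance, else None."""
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    ppm = (obs_mz - theo_mh) / theo_mh * 1e6
    return ppm if abs(ppm) <= tol_ppm else None


def match_fragments(
    spectrum: Spectrum, ions: Sequence[FragmentIon], tol_da: float = 0.6
) -> list[tuple[FragmentIon, tuple[float, float]]]:
    """Greedy one-peak-one-ion assignment within an absolute tolerance.

    Candidate (ion, peak) pairs are taken in order of |Δm/z|, ties broken by
    lower ion index; each observed peak and each ion is used at most once.
    """
    if tol_da <= 0:
        raise ValueError("tol_da must be positive")
    candidates = []
    for k, ion in enumerate(ions):
        for j, (mz, inten) in enumerate(spectrum.peaks):
            d = abs(mz - ion.mz)
            if d <= tol_da:
                candidates.append((d, ion.index, k, j))
    candidates.sort()
    used_ions: set[int] = set()
    used_peaks: set[int] = set()
    matches = []
    for d, _, k, j in candidates:
        if k in used_ions or j in used_peaks:
            continue
        used_ions.add(k)
        used_peaks.add(j)
        matches.append((ions[k], spectrum.peaks[j]))
    return matches


def score_psm(
    n_matched: int,
    n_theoretical: int,
    n_peaks: int,
    mz_range: float,
    tol_da: float,
) -> float:
    """-log10 binomial tail P(X >= n_matched), X ~ Bin(n_theoretical, p).

    p is the per-ion probability that a uniformly placed peak falls within
    the tolerance window: ``min(1, n_peaks * 2 * tol_da / mz_range)``.
    """
    if min(n_matched, n_theoretical, n_peaks) < 0 or mz_range <= 0:
        raise ValueError("counts must be >= 0 and mz_range positive")
    if n_matched == 0:
        return 0.0
    p = min(1.0, n_peaks * 2.0 * tol_da / mz_range)
    if p == 0.0:
        return math.inf
    logp = binom.logsf(n_matched - 1, n_theoretical, p)
    return -logp / math.log(10)


# ---------------------------------------------------------------------------
# Search


def _best_precursor_match(
    spectrum: Spectrum, variant: TheoreticalPeptideMass, cfg: SearchConfig
) -> Optional[float]:
    """Smallest-|ppm| precursor match among a survey spectrum's peaks."""
    best = None
    for mz, _ in spectrum.peaks:
        ppm = match_precursor(mz, variant.mh_plus, cfg.tol_ppm)
        if ppm is not None and (best is None or abs(ppm) < abs(best)):
            best = ppm
    return best


def search(
    spectra: Iterable[Spectrum],
    library: Sequence[TheoreticalPeptideMass],
    config: Optional[SearchConfig] = None,
) -> list[PeptideSpectrumMatch]:
    """Match a theoretical peptide library against spectra.

    Survey spectra are matched by precursor mass only (scored with a
    single-trial binomial window); fragment spectra by precursor mass then
    fragment ions.  The best PSM per spectrum above the score threshold is
    retained.
    """
    cfg = config or SearchConfig()
    library = list(library)
    if not library:
        logger.warning("empty theoretical library: no PSMs can be produced")
        return []
    lo, hi = cfg.mz_range
    span = hi - lo
    results = []
    for spectrum in spectra:
        best: Optional[PeptideSpectrumMatch] = None
        for variant in library:
            if spectrum.level == 1:
                ppm = _best_precursor_match(spectrum, variant, cfg)
                if ppm is None:
                    continue
                window = variant.mh_plus * cfg.tol_ppm * 1e-6
                score = score_psm(1, 1, len(spectrum.peaks), span, window)
                psm = PeptideSpectrumMatch(
                    variant, spectrum.id, spectrum.tissue, 0, 0, ppm, score
                )
            else:
                if spectrum.precursor_mz is None:
                    continue
                ppm = match_precursor(spectrum.precursor_mz, variant.mh_plus, cfg.tol_ppm)
                if ppm is None:
                    continue
                if len(variant.variant_sequence) < 2:
                    continue
                ions = fragment_ions(
                    variant.variant_sequence,
                    variant.mods,
                    series_set=cfg.series_set,
                    max_charge=cfg.max_charge,
                )
                matched = match_fragments(spectrum, ions, cfg.tol_da)
                score = score_psm(
                    len(matched), len(ions), len(spectrum.peaks), span, cfg.tol_da
                )
                psm = PeptideSpectrumMatch(
                    variant, spectrum.id, spectrum.tissue, len(matched), len(ions), ppm, score
                )
            if psm.score >= cfg.score_threshold and (
                best is None
                or psm.score > best.score
                or (psm.score == best.score and abs(psm.ppm_error_precursor) < abs(best.ppm_error_precursor))
            ):
                best = psm
        if best is not None:
            results.append(best)
    return results


def detection_table(
    psms: Iterable[PeptideSpectrumMatch],
    peptide_names: Optional[Sequence[str]] = None,
    tissues: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Boolean peptide × tissue presence matrix.

    Rows follow ``peptide_names`` when given (the FLGa 1..6 convention is a
    natural-sort of the names), columns follow ``tissues``.
    """
    psms = list(psms)

    def pep_key(psm: PeptideSpectrumMatch) -> str:
        return psm.variant.peptide.name or psm.variant.variant_sequence

    seen_peps = sorted({pep_key(p) for p in psms})
    seen_tissues = sorted({p.tissue for p in psms})
    rows = list(peptide_names) if peptide_names is not None else seen_peps
    cols = list(tissues) if tissues is not None else seen_tissues
    for p in seen_peps:
        if p not in rows:
            rows.append(p)
    for t in seen_tissues:
        if t not in cols:
            cols.append(t)
    table = pd.DataFrame(False, index=pd.Index(rows, name="peptide"), columns=cols)
    for psm in psms:
        table.loc[pep_key(psm), psm.tissue] = True
    return table


def psms_to_frame(psms: Iterable[PeptideSpectrumMatch]) -> pd.DataFrame:
    rows = [
        {
            "spectrum_id": p.spectrum_id,
            "tissue": p.tissue,
            "peptide": p.variant.peptide.name or p.variant.variant_sequence,
            "sequence": p.variant.variant_sequence,
            "mods": ";".join(
                f"{pl.mod.name}@{pl.site}" if pl.site else pl.mod.name for pl in p.variant.mods
            ),
            "mh_plus": round(p.variant.mh_plus, 5),
            "n_matched": p.n_matched,
            "n_theoretical": p.n_theoretical,
            "ppm_error": round(p.ppm_error_precursor, 3),
            "score": round(p.score, 4),
        }
        for p in psms
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "spectrum_id", "tissue", "peptide", "sequence", "mods",
            "mh_plus", "n_matched", "n_theoretical", "ppm_error", "score",
        ],
    )
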