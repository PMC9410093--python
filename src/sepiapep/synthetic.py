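"""Ground-truthed synthetic data: precursors, peak lists and FPKM tables.

The generator emulates the structure the pipeline assumes — prohormones
with a hydrophobic signal peptide and payload peptides flanked by
di-/tribasic convertase sites (including a multi-copy payload, mirroring
the seven-fold repeat on the FLGa A precursor); centroided MALDI-style peak
lists with Gaussian relative (ppm) precursor mass error, partial fragment
retention and uniform background noise; and FPKM tables with CNS-dominant
targets over a constitutive reference.  Every dataset is reproducible from
(config, seed) and ships with a manifest sufficient to score pipeline
output exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .chem import enumerate_variants, mh_plus, fragment_ions
from .prohormone import MaturePeptide, Precursor
from .spectra import Spectrum, DEFAULT_MZ_RANGE
from .expression import DEFAULT_TISSUE_PANEL, DEFAULT_CNS_TISSUES

# spacers and payloads exclude K/R so payload boundaries are unambiguous
PAYLOAD_ALPHABET = "ACDEFGHILMNPQSTVWY"
HYDROPHOBIC = "LIVFA"
DIBASIC = ("KR", "KK", "RR", "RK")
TRIBASIC = ("KRR", "KKR", "RKR")


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study.

    Defaults mirror the biological structure being emulated: six payload
    peptides per precursor with one payload carried in seven copies, about
    half of the internal payloads amidated, MALDI survey accuracy with a
    30 ppm error s.d., and a CNS-dominant expression pattern over an
    eight-tissue panel.
    """

    seed: int
    n_precursors: int = 2
    n_payloads: int = 6
    payloads: Optional[Sequence[str]] = None  # explicit payloads, or None = random
    payload_len_range: tuple[int, int] = (8, 22)
    repeat_payload_index: int = 2  # 0-based index of the multi-copy payload
    repeat_copies: int = 7
    amidated_fraction: float = 0.5
    tribasic_fraction: float = 0.2
    signal_len_range: tuple[int, int] = (12, 24)
    min_len: int = 4
    # spectra
    ppm_error_sd: float = 30.0
    fragment_da_sd: float = 0.1
    fragment_retention_prob: float = 0.8
    noise_peaks_per_spectrum: int = 30
    mz_range: tuple[float, float] = DEFAULT_MZ_RANGE
    cns_presence_prob: float = 0.9
    peripheral_presence_prob: float = 0.3
    n_noise_spectra: int = 0
    # fpkm
    tissue_panel: tuple[str, ...] = DEFAULT_TISSUE_PANEL
    cns_tissues: frozenset = DEFAULT_CNS_TISSUES
    target_patterns: tuple[str, ...] = ("CNS_restricted", "CNS_dominant", "broad", "silent")
    cns_mean_fpkm: float = 200.0
    peripheral_mean_fpkm: float = 2.0
    reference_mean_fpkm: float = 100.0
    nb_dispersion: float = 5.0  # gamma shape of the gamma-Poisson noise

    def __post_init__(self) -> None:
        for p in (
            self.amidated_fraction, self.tribasic_fraction,
            self.fragment_retention_prob, self.cns_presence_prob,
            self.peripheral_presence_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    def rng(self, stream: str) -> np.random.Generator:
        import zlib

        return np.random.default_rng([self.seed, zlib.crc32(stream.encode())])


@dataclass
class Manifest:
    """Ground truth for one generated bundle (JSON-serializable)."""

    precursors: list = field(default_factory=list)
    peptides: list = field(default_factory=list)
    spectra: list = field(default_factory=list)
    detection: dict = field(default_factory=dict)  # peptide name -> [tissues]
    transcripts: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "Manifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _random_payload(rng: np.random.Generator, length: int, end_g_ok: bool) -> str:
    letters = list(PAYLOAD_ALPHABET)
    seq = "".join(rng.choice(letters, size=length))
    while not end_g_ok and seq.endswith("G"):
        seq = seq[:-1] + str(rng.choice([c for c in letters if c != "G"]))
    return seq


def _random_site(rng: np.random.Generator, tribasic_fraction: float) -> str:
    if rng.random() < tribasic_fraction:
        return str(rng.choice(TRIBASIC))
    return str(rng.choice(DIBASIC))


def gen_precursors(config: GeneratorConfig) -> tuple[list[Precursor], Manifest]:
    """Generate precursors with embedded payload peptides.

    Layout: signal peptide, a short sub-min_len spacer, then payloads
    separated by di-/tribasic sites; the repeat payload appears
    ``repeat_copies`` times consecutively; the final payload sits at the
    C-terminus and is never amidated.
    """
    rng = config.rng("precursors")
    manifest = Manifest()
    precursors = []
    for pi in range(config.n_precursors):
        if config.payloads is not None:
            payloads = list(config.payloads)
        else:
            payloads = []
            while len(payloads) < config.n_payloads:
                length = int(rng.integers(*config.payload_len_range))
                seq = _random_payload(rng, length, end_g_ok=False)
                if seq not in payloads:
                    payloads.append(seq)
        n = len(payloads)
        amidated = [False] * n
        internal = list(range(n - 1))  # terminal payload never amidated
        k_amid = int(round(config.amidated_fraction * len(internal)))
        for idx in list(rng.choice(internal, size=k_amid, replace=False)) if k_amid else []:
            amidated[int(idx)] = True

        sig_len = int(rng.integers(*config.signal_len_range))
        signal = "".join(rng.choice(list(HYDROPHOBIC), size=sig_len - 1)) + "A"
        spacer = "".join(rng.choice(list("DEST"), size=int(rng.integers(1, config.min_len))))

        parts = [signal, spacer]
        true_peps = []
        order = []
        for j, seq in enumerate(payloads):
            copies = config.repeat_copies if j == config.repeat_payload_index and n > 1 else 1
            for _ in range(copies):
                order.append(j)
        pid = f"SYN_{pi + 1}"
        for rank, j in enumerate(order):
            terminal = rank == len(order) - 1
            parts.append(_random_site(rng, config.tribasic_fraction))
            segment = payloads[j] + ("G" if amidated[j] and not terminal else "")
            parts.append(segment)
            true_peps.append(
                {
                    "precursor": pid,
                    "sequence": payloads[j],
                    "amidated": bool(amidated[j] and not terminal),
                    "payload_index": j,
                }
            )
        sequence = "".join(parts)
        precursors.append(Precursor(id=pid, sequence=sequence, signal_end=sig_len))
        manifest.precursors.append(
            {"id": pid, "sequence": sequence, "signal_end": sig_len, "payloads": payloads}
        )
        manifest.peptides.extend(true_peps)
    return precursors, manifest


def manifest_peptides(manifest: Manifest) -> list[MaturePeptide]:
    """Distinct mature peptides recorded in a manifest, as domain objects
    named SYN 1..k per precursor in order of first appearance."""
    out = []
    seen = {}
    for rec in manifest.peptides:
        key = (rec["sequence"], rec["amidated"])
        if key in seen:
            continue
        seen[key] = True
        out.append(
            MaturePeptide(
                sequence=rec["sequence"],
                amidated=rec["amidated"],
                pyroglutamate=rec["sequence"].startswith("Q"),
                source_precursor=rec["precursor"],
                name=f"SYN {len(seen)}",
            )
        )
    return out


def gen_spectra(
    config: GeneratorConfig, peptides: Sequence[MaturePeptide]
) -> tuple[list[Spectrum], Manifest]:
    """Generate per-tissue survey and fragment spectra for peptides.

    Each peptide present in a tissue (CNS tissues with probability
    ``cns_presence_prob``, peripheral with ``peripheral_presence_prob``)
    yields one fragment spectrum: a precursor m/z with Gaussian relative
    error of ``ppm_error_sd`` ppm, each a/b/y ion retained with
    ``fragment_retention_prob`` (Gaussian Da jitter), plus uniform noise
    peaks.  One survey spectrum per tissue carries all present [M+H]+
    peaks.  ``n_noise_spectra`` pure-noise fragment spectra are appended.
    """
    rng = config.rng("spectra")
    lo, hi = config.mz_range
    manifest = Manifest()
    spectra = []
    counter = 0

    for tissue in config.tissue_panel:
        present = []
        for pep in peptides:
            p = (
                config.cns_presence_prob
                if tissue in config.cns_tissues
                else config.peripheral_presence_prob
            )
            if rng.random() < p:
                present.append(pep)
        survey_peaks = []
        for pep in present:
            mods = enumerate_variants(pep)[0].mods  # unmodified base variant
            mh = mh_plus(pep.sequence, mods)
            if not (lo <= mh <= hi):
                continue
            eps = rng.normal(0.0, config.ppm_error_sd * 1e-6)
            obs_mh = mh * (1.0 + eps)
            survey_peaks.append((obs_mh, float(rng.uniform(50, 500))))

            counter += 1
            sid = f"ms2_{counter}"
            peaks = []
            ions = fragment_ions(pep.sequence, mods, ("a", "b", "y"), max_charge=1)
            kept = 0
            for ion in ions:
                if rng.random() < config.fragment_retention_prob:
                    # fragment spectra span below the survey window, so no clipping
                    mz = ion.mz + rng.normal(0.0, config.fragment_da_sd)
                    peaks.append((mz, float(rng.uniform(50, 500))))
                    kept += 1
            for _ in range(config.noise_peaks_per_spectrum):
                peaks.append((float(rng.uniform(lo, hi)), float(rng.uniform(1, 50))))
            spectra.append(
                Spectrum(id=sid, tissue=tissue, level=2, peaks=peaks, precursor_mz=obs_mh)
            )
            manifest.spectra.append(
                {
                    "id": sid,
                    "tissue": tissue,
                    "peptide": pep.name or pep.sequence,
                    "sequence": pep.sequence,
                    "amidated": pep.amidated,
                    "true_mh": mh,
                    "retained_fragments": kept,
                    "n_theoretical": len(ions),
                }
            )
            manifest.detection.setdefault(pep.name or pep.sequence, [])
            if tissue not in manifest.detection[pep.name or pep.sequence]:
                manifest.detection[pep.name or pep.sequence].append(tissue)
        if survey_peaks:
            for _ in range(config.noise_peaks_per_spectrum):
                survey_peaks.append((float(rng.uniform(lo, hi)), float(rng.uniform(1, 50))))
            counter += 1
            spectra.append(
                Spectrum(id=f"ms1_{counter}", tissue=tissue, level=1, peaks=survey_peaks)
            )

    for _ in range(config.n_noise_spectra):
        counter += 1
        peaks = [
            (float(rng.uniform(lo, hi)), float(rng.uniform(1, 50)))
            for _ in range(config.noise_peaks_per_spectrum)
        ]
        spectra.append(
            Spectrum(
                id=f"noise_{counter}",
                tissue="noise",
                level=2,
                peaks=peaks,
                precursor_mz=float(rng.uniform(lo, hi)),
            )
        )
    return spectra, manifest


def gen_fpkm(config: GeneratorConfig):
    """Generate an FPKM table: a constitutive reference plus one target
    transcript per configured pattern, with gamma-Poisson (negative-
    binomial-style) noise on nonzero cells.  Returns (DataFrame, Manifest).
    """
    import pandas as pd

    rng = config.rng("fpkm")
    manifest = Manifest()
    rows = {}

    def nb(mean: float) -> float:
        lam = rng.gamma(config.nb_dispersion, mean / config.nb_dispersion)
        return float(rng.poisson(lam))

    ref = {t: nb(config.reference_mean_fpkm) + 1.0 for t in config.tissue_panel}
    rows["reference"] = ref
    manifest.transcripts.append({"id": "reference", "pattern": "reference"})

    for i, pattern in enumerate(config.target_patterns, start=1):
        tid = f"target_{i}_{pattern}"
        vals = {}
        for t in config.tissue_panel:
            is_cns = t in config.cns_tissues
            if pattern == "silent":
                vals[t] = 0.0
            elif pattern == "CNS_restricted":
                vals[t] = nb(config.cns_mean_fpkm) if is_cns else 0.0
            elif pattern == "CNS_dominant":
                vals[t] = nb(config.cns_mean_fpkm) if is_cns else nb(config.peripheral_mean_fpkm)
            elif pattern == "broad":
                vals[t] = nb(config.reference_mean_fpkm) + 1.0
            else:
                raise ValueError(f"unknown pattern {pattern!r}")
        rows[tid] = vals
        manifest.transcripts.append({"id": tid, "pattern": pattern})

    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(config.tissue_panel))
    df.index.name = "transcript_id"
    return df, manifest
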