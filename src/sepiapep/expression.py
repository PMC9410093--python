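"""Tissue expression profiling from FPKM tables.

An expression profile is a transcript's FPKM value (fragments per kilobase
of exon per million mapped fragments) across a declared tissue panel.
Profiles are normalized against a constitutively expressed reference
transcript (elongation-factor style) and classified by how strongly
expression is restricted to the central nervous system.  Values represent
pooled animals, so classification is descriptive: no replicate statistics
are attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_TISSUE_PANEL = ("ANG", "MNG", "OvG", "PSG", "OL", "SupEM", "SubEM", "OG")
DEFAULT_CNS_TISSUES = frozenset({"OL", "SupEM", "SubEM"})


@dataclass(frozen=True)
class ExpressionProfile:
    transcript_id: str
    fpkm: Mapping[str, float]
    reference_id: Optional[str] = None

    def __post_init__(self) -> None:
        bad = {t: v for t, v in self.fpkm.items() if v < 0}
        if bad:
            raise ValueError(f"{self.transcript_id}: negative FPKM in {sorted(bad)}")

    @property
    def tissues(self) -> tuple[str, ...]:
        return tuple(self.fpkm)

    def total(self) -> float:
        return float(sum(self.fpkm.values()))


def load_fpkm(path) -> list[ExpressionProfile]:
    """Parse a transcript × tissue FPKM TSV (header row of tissue labels,
    one row per transcript).  Missing cells are read as 0 with a warning;
    duplicated transcript ids are an error."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicated transcript rows: {dups}")
    if df.isna().any().any():
        logger.warning("missing FPKM cells read as 0")
        df = df.fillna(0.0)
    return [
        ExpressionProfile(transcript_id=str(tid), fpkm={str(t): float(v) for t, v in row.items()})
        for tid, row in df.iterrows()
    ]


def profiles_to_frame(profiles: Iterable[ExpressionProfile]) -> pd.DataFrame:
    data = {p.transcript_id: p.fpkm for p in profiles}
    df = pd.DataFrame.from_dict(data, orient="index")
    df.index.name = "transcript_id"
    return df


def write_fpkm(profiles: Iterable[ExpressionProfile], path) -> None:
    profiles_to_frame(profiles).to_csv(path, sep="\t")


def normalize(profile: ExpressionProfile, reference: ExpressionProfile) -> dict[str, float]:
    """Per-tissue FPKM ratio target/reference; tissues where the reference
    is zero are omitted with a warning."""
    ratios = {}
    skipped = []
    for tissue, value in profile.fpkm.items():
        ref = reference.fpkm.get(tissue, 0.0)
        if ref > 0:
            ratios[tissue] = value / ref
        else:
            skipped.append(tissue)
    if skipped:
        logger.warning(
            "reference %s has zero FPKM in %s; ratios omitted",
            reference.transcript_id, skipped,
        )
    return ratios


def classify_restriction(
    profile: ExpressionProfile,
    cns_tissues: Iterable[str] = DEFAULT_CNS_TISSUES,
    dominance: float = 0.9,
) -> str:
    """Classify a profile's CNS restriction.

    silent: all FPKM 0; CNS_restricted: every non-CNS tissue 0;
    CNS_dominant: CNS share of total FPKM >= ``dominance``; else broad.
    Scale-invariant by construction.
    """
    cns = set(cns_tissues)
    total = profile.total()
    if total == 0:
        return "silent"
    if all(v == 0 for t, v in profile.fpkm.items() if t not in cns):
        return "CNS_restricted"
    cns_share = sum(v for t, v in profile.fpkm.items() if t in cns) / total
    if cns_share >= dominance:
        return "CNS_dominant"
    return "broad"


def plot_profile(
    profile: ExpressionProfile,
    reference: Optional[ExpressionProfile] = None,
    path=None,
):
    """Bar chart of a profile (reference gene, when given, in orange)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    tissues = list(profile.tissues)
    x = np.arange(len(tissues))
    fig, ax = plt.subplots(figsize=(8, 4))
    width = 0.4 if reference is not None else 0.8
    ax.bar(x - (width / 2 if reference is not None else 0),
           [profile.fpkm[t] for t in tissues], width, label=profile.transcript_id)
    if reference is not None:
        ax.bar(x + width / 2, [reference.fpkm.get(t, 0.0) for t in tissues],
               width, color="orange", label=reference.transcript_id)
    ax.set_xticks(x)
    ax.set_xticklabels(tissues, rotation=45, ha="right")
    ax.set_ylabel("FPKM")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
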