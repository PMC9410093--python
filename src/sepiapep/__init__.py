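"""sepiapep: neuropeptide prohormone processing and peptidomics toolkit.

Predicts mature neuropeptides from prohormone sequences (basic cleavage
sites, C-terminal amidation, pyroglutamate), computes theoretical masses
and a/b/y fragment series, matches them against centroided peak lists,
classifies peptides into orcokinin/FCAN motif families, and profiles
tissue FPKM expression.  A seeded synthetic-data generator provides
ground-truthed inputs for every stage.
"""

from importlib import resources

__version__ = "0.1.0"

from . import chem, config, expression, motif, prohormone, spectra, synthetic  # noqa: F401


def packaged_precursor_fasta():
    """Path-like handle to the packaged synthetic FLGa precursor fixture.

    The two precursors are synthetic reconstructions of the published
    FLGa A / FLGa B prohormones, honoring every printed constraint (FLGa 1
    21-mer, antigen cores, copy counts, amidation pattern); the full
    figure sequences are not public text.
    """
    return resources.files("sepiapep").joinpath("data/flga_precursors_synthetic.fasta")
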