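# Methods

## Prohormone processing model

Precursors are processed under the canonical secretory-pathway model:
signal peptidase removes the N-terminal signal peptide, prohormone
convertases cut at runs of basic residues (K/R), and carboxypeptidase E
trims the exposed basic residues. Mature peptides are therefore the
maximal segments strictly between basic runs, with the flanking basics
removed; coordinates are 1-based inclusive and `*` stop marks are
stripped at parse time.

Rules and defaults:

- **Cleavage sites.** Maximal K/R runs of length 2–3 are di-/tribasic
  sites. Monobasic cleavage exists in vivo but is rarer and
  context-dependent; it is off by default and exposed as a flag. Runs
  longer than 3 are collapsed to a single tribasic site anchored at the
  C-terminal end of the run, so no zero-length peptide is ever produced;
  the leftover basics then remain on the upstream segment. This regime
  does not occur in the packaged fixtures or the generator output.
- **Amidation.** A segment ending in G that is followed by a cleavage
  site (not the precursor terminus) donates that glycine: the G is
  stripped and the peptide flagged amidated (−0.98402 Da on the mass).
  A terminal segment is never amidated, which is how the family's
  unamidated last peptide arises from the same rule.
- **Pyroglutamate.** An N-terminal Q flags a *possible* pyroglutamate;
  both forms are kept and resolved during variant enumeration, mirroring
  variable-modification search practice.
- **min_len.** Segments shorter than 4 residues (pre-PTM) are discarded
  as linker/spacer material; configurable.
- **Signal peptide.** A hydrophobicity heuristic: the 8–15-residue core
  with maximal mean Kyte–Doolittle hydropathy within the first 40
  residues must reach a mean of 1.6; the cut is placed after the first
  small residue (A/G/S/C) downstream of the core. This is deliberately
  simple — no machine-learned predictor — so fixture files may carry a
  curated `signal_end=N` tag that takes precedence, and tests of peptide
  counts do not depend on the heuristic.

## Precursor fixture

The two packaged precursors (`data/flga_precursors_synthetic.fasta`) are
**synthetic reconstructions**: the published full precursor sequences
exist only as figure images. The reconstruction fixes everything that is
printed as text — the 21-residue FLGa 1 chain `GAESGEAHVFDSLGGGHVPYY`,
the FLGa 2 antigen core `VFDTLGGGHVPYY` and FLGa 3 antigen
`FDSLGGGSFLG-amide`, the PYY C-termini of FLGa 1/2, amidation of
FLGa 3–5, an unamidated terminal FLGa 6, seven FLGa 3 copies on
precursor A and eight on B — and invents only the unprinted remainder
(signal peptide, FLGa 4/5/6 full sequences) consistently with the family
motif. Conclusions that depend on the invented parts are never asserted.

## Mass arithmetic

Residue masses (monoisotopic and average) and the modification catalogue
are packaged TSV resources; monoisotopic values are cross-checked in the
tests against an independent proteomics library to 1e-4 Da. Average
masses follow the classic residue-average table and may differ from
other libraries' atomic-weight choices by ~1–2 mDa per residue. m/z
arithmetic uses the proton mass 1.007276 Da ([M+H]⁺ MALDI convention),
water 18.010565 Da, CO 27.99491 Da. Fragment series: b_i = prefix sum +
proton, a_i = b_i − CO, y_i = suffix sum + water + proton; terminal
modifications stay with their terminus, so C-terminal amide shifts only
the y series. Full-length b_n/a_n ions are not generated (a/b indices
run to n−1); the a-series example identity a_i = b_i − CO is therefore
exercised on internal indices. Charge states up to 2 via (m + zH)/z;
MALDI is predominantly singly charged. Dioxidation is restricted to Met,
an assumption the modification table records explicitly.

## Spectrum matching and scoring

The search is enzyme-free: the library is every predicted mature peptide
expanded over its modification variants. Survey (level-1) spectra match
by precursor mass within 200 ppm; fragment (level-2) spectra match the
precursor, then assign peaks to theoretical ions greedily — candidates
ordered by |Δm/z|, ties by lower ion index, each peak and each ion used
at most once (this avoids inflating counts from isotope clusters) — at
0.6 Da. Both tolerances are the standard MALDI-TOF/TOF search settings
and are configurable.

The PSM score is the −log10 binomial tail of the matched-ion count under
a uniform-peak null (p = min(1, 2Nτ/R)). It is intensity-free and is a
simple, defensible stand-in for commercial probabilistic search scores,
**not** a reimplementation of one; there is no target-decoy FDR in v1.
The default score threshold (3.0) was calibrated on the packaged
noise-only simulation so that the false-positive rate is ≤1%; it lives
in the configuration, not in code. Survey-spectrum matches score near
−log10 of a single window probability (≈2–2.5 under default noise
levels) and thus fall below the default threshold: detection tables are
driven by fragment evidence, as in practice.

## Motif layer

Patterns are ordered residue classes (`D S (I/L) G G G`), scanned
exactly with overlaps reported. The packaged library carries two
orcokinin-B entries: the strict hexapeptide `DS(L/I)GGG` used for
position assertions, and a family-core class `D(S/T)(L/I)GGG` used by
the classifier — the second family member carries Thr at the Ser
position, and a strict pattern would misclassify it as non-orcokinin-B
while the whole family is one clade. The orcokinin-C core and FCAN
consensus entries are synthetic stand-ins (the published consensus
figures are images); classification quality is asserted only on
sequences whose text is printed.

Global alignment is affine-gap (BLOSUM62, open −10, extend −1, a gap of
length L costs open + (L−1)·extend, end gaps penalized) with a
deterministic first-optimal traceback; tests verify the score against an
exhaustive enumeration of all alignments on short pairs. Multiple
alignment is progressive pairwise against the first sequence — adequate
for short, near-identical peptide blocks, documented as not a general
MSA.

Consensus construction: per column, a fixed residue at ≥80% frequency; a
two-residue class when the top two jointly reach 80% **and** are a
conservative pair (positive BLOSUM62 score, e.g. L/I or S/T); otherwise
a wildcard. The conservative-pair condition keeps biochemically
meaningless splits (e.g. an A/C dichotomy) from being promoted to
classes; all-gap columns are dropped.

Family cascade: orcokinin_B on any B-core hit; else orcokinin_C on the
C-core pattern; else FCAN when alignment identity to the FCAN consensus
reaches 0.5; else unclassified. Evidence (motif positions, identities)
is recorded on every call.

## Expression profiling

FPKM values represent pooled animals, so the classifier is descriptive:
silent (all zero), CNS_restricted (every non-CNS tissue zero),
CNS_dominant (CNS share of total ≥0.9), else broad. The call is
scale-invariant. Ratios to a constitutive reference transcript are
reported per tissue, omitting tissues where the reference is zero. The
default panel is ANG, MNG, OvG, PSG, OL, SupEM, SubEM, OG with OL,
SupEM, SubEM as the CNS set.

## Synthetic data generator

The generator emulates exactly the structure the pipeline assumes, so a
pipeline error cannot hide behind data mismatch:

- **Precursors** — hydrophobic signal peptide (12–24 residues, ending in
  a small residue), a sub-min_len acidic spacer, then six payload
  peptides (8–22 residues) separated by di-/tribasic sites (20%
  tribasic); the third payload repeated seven times (mirroring the
  family's multi-copy peptide); about half of the internal payloads
  amidated via an appended G; the terminal payload never amidated.
  Payloads and spacers exclude K/R so ground truth is unambiguous, and
  non-amidated payloads never end in G so the amidation rule cannot
  mis-fire.
- **Spectra** — per tissue, each peptide is present with probability 0.9
  (CNS) or 0.3 (peripheral). Each present peptide yields one fragment
  spectrum: precursor m/z with Gaussian *relative* error (s.d. 30 ppm),
  each a/b/y ion retained with probability 0.8 plus 0.1 Da Gaussian
  jitter, 30 uniform noise peaks; one survey spectrum per tissue carries
  all present [M+H]⁺ peaks within the 700–4000 Da window. Fragment
  peaks are not clipped to the survey window (MS/MS spectra extend
  below it). Pure-noise spectra are available for null calibration.
  No LC retention, isotope envelopes or detector saturation are
  simulated — so passing tests demonstrate correctness of the matching
  arithmetic and bookkeeping, not robustness to real instrument
  artefacts.
- **FPKM** — a constitutive reference plus one target per pattern
  (CNS_restricted / CNS_dominant / broad / silent), gamma-Poisson
  (negative-binomial-style) noise on nonzero cells; CNS mean 200,
  peripheral mean 2, reference mean 100.

Everything derives from `(config, seed)` through independent named
streams, so datasets are byte-reproducible and adding one stage does not
shift another's draws. The manifest (JSON) stores true precursors,
peptides with PTMs, per-spectrum embedded peptide and true m/z, and
per-transcript truth patterns.

## Problem sizes

Defaults produce 2 precursors × 12 distinct peptides, ~55 fragment
spectra plus 8 survey spectra, and 300 noise spectra for the null; the
full test suite and the acceptance script each complete in seconds.
These sizes give stable sensitivity/false-positive estimates (55 true
pairs, 300 nulls) while staying trivially cheap to re-run.

## Known limitations

- The signal-peptide heuristic is a hydrophobicity rule, not a trained
  predictor; curated `signal_end` tags take precedence.
- No target-decoy FDR; the binomial score threshold is a null-simulation
  calibration, not an error-rate guarantee on real data.
- Splice relationships between precursor variants are not modelled; the
  two fixtures are stored verbatim.
- The progressive aligner anchors on the first sequence and can be
  order-sensitive for divergent inputs.
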