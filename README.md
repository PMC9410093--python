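# sepiapep

Neuropeptide prohormone processing and peptidomics for cephalopod
orcokinin-B (FLGamide) peptides.

Cuttlefish (*Sepia officinalis*) egg-laying is modulated by a family of
neuropeptides — FLGa 1–6, since renamed So-orcokinin B — that are cleaved
from two near-identical prohormones and detected by MALDI-TOF/TOF
peptidomics in the genital tract and central nervous system. `sepiapep`
implements the in-silico arm of that kind of study as a reusable pipeline,
for peptidomics researchers working on invertebrate neuropeptides:

1. **Prohormone processing** (`sepiapep.prohormone`) — signal-peptide
   heuristic, detection of di-/tribasic convertase sites (runs of K/R),
   excision of mature peptides, C-terminal amidation (Gly-donor rule,
   −0.98402 Da) and N-terminal pyroglutamate flags, copy counting.
2. **Peptide chemistry** (`sepiapep.chem`) — monoisotopic/average masses,
   a modification catalogue, [M+H]⁺ and a/b/y fragment-ion series.
3. **Spectrum matching** (`sepiapep.spectra`) — no-enzyme search of
   centroided peak lists (MGF or two-column text) at 200 ppm precursor /
   0.6 Da fragment tolerance, binomial-tail PSM scoring, per-tissue
   detection tables.
4. **Motif families** (`sepiapep.motif`) — degenerate-motif scanning for
   the DS(L/I)GGG orcokinin-B hexapeptide, affine-gap global alignment
   (BLOSUM62), consensus patterns, and the orcokinin-B / orcokinin-C /
   FCAN rule cascade.
5. **Expression profiling** (`sepiapep.expression`) — FPKM tables
   normalized to a reference transcript and classified as
   silent / CNS_restricted / CNS_dominant / broad.
6. **Synthetic data** (`sepiapep.synthetic`) — a seeded generator of
   ground-truthed precursors, spectra and FPKM tables, with a manifest
   that scores any pipeline output exactly.

## The model in brief

Mature peptides are the maximal segments strictly between basic runs
(prohormone convertase + carboxypeptidase-E model); a segment ending in G
followed by a cleavage site yields the amide of the preceding residue
(PAM). For identification, a peptide variant with theoretical ions
T = {a_i, b_i, y_i} is matched to a spectrum of N peaks over an m/z span R
at tolerance τ; with p = min(1, 2Nτ/R), the PSM score is

    score = −log10 P(X ≥ k),  X ~ Binomial(|T|, p)

where k is the number of matched ions under greedy one-peak-one-ion
assignment.

## Worked example

The packaged precursor file is a synthetic reconstruction of the two
FLGa prohormones (the published figure sequences are images; the
reconstruction honors every printed constraint — see
`docs/methods.md`).

```
$ sepiapep predict precursors.fasta -o peptides.tsv
25 peptides from 2 precursors -> peptides.tsv

$ head -4 peptides.tsv
precursor_id  name    start  end  sequence               amidated  pyroglu  copy_index
FLGa_A        FLGa 1  16     36   GAESGEAHVFDSLGGGHVPYY  False     False    1
FLGa_A        FLGa 2  39     59   GTDSGDGHVFDTLGGGHVPYY  False     False    1
FLGa_A        FLGa 3  62     73   FDSLGGGSFLG            True      False    1
```

FLGa A yields 6 distinct peptides, 7 of them copies of the amidated
FLGa 3 (`FDSLGGGSFLG`, [M+H]⁺ 1055.5156); FLGa B carries one extra
FLGa 3 copy. FLGa 1 is the 21-residue `GAESGEAHVFDSLGGGHVPYY`
([M+H]⁺ 2148.9621), carrying the orcokinin-B hexapeptide at position 11:

```
$ sepiapep classify peptides.tsv -o families.tsv
$ head -3 families.tsv
name    sequence               family       evidence
FLGa 1  GAESGEAHVFDSLGGGHVPYY  orcokinin_B  orcokinin_B_core@11;flgamide_hexapeptide@11
FLGa 2  GTDSGDGHVFDTLGGGHVPYY  orcokinin_B  orcokinin_B_core@11
```

A full synthetic round trip (generate → predict → search → detect):

```
$ sepiapep simulate --seed 1 --out-dir bundle
$ sepiapep predict bundle/precursors.fasta -o syn.tsv --name-prefix SYN
$ sepiapep search syn.tsv bundle/spectra.mgf --psms-out psms.tsv --detection-out detection.tsv
55 PSMs -> psms.tsv; detection table -> detection.tsv
```

The detection table reproduces `bundle/manifest.json` exactly at the
default conditions (30 ppm simulated precursor error, 80% fragment
retention, 30 noise peaks per spectrum).

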