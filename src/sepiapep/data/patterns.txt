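# Packaged motif-pattern library.
# Format: one pattern per line -- name, then one token per column.
# Tokens: a fixed residue, a class "(X/Y)", or "." (wildcard).
#
# flgamide_hexapeptide is the strict orcokinin-B hexapeptide DS(L/I)GGG.
# orcokinin_B_core widens the Ser position to the conservative (S/T) class
# so that family members carrying DT(L/I)GGG are still recognised.
# The orcokinin_C core and the FCAN consensus are SYNTHETIC stand-ins
# reconstructed from family descriptions (glycine-rich core with distinct
# flanks; FCAN divergent from both), not transcriptions of published
# alignment figures.
flgamide_hexapeptide D S (I/L) G G G
orcokinin_B_core D (S/T) (I/L) G G G
orcokinin_C_core N (F/Y) D E (I/V) D . (S/T) G G G
FCAN_consensus S G Q W Q R N P N A F R M
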