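>FLGa_A signal_end=15 is_partial=no synthetic=yes
MKWLVLFAVLAVSSAGAESGEAHVFDSLGGGHVPYYKRGTDSGDGHVFDTLGGGHVPYYK
RFDSLGGGSFLGGKRFDSLGGGSFLGGKRFDSLGGGSFLGGKRFDSLGGGSFLGGKRFDS
LGGGSFLGGKRFDSLGGGSFLGGKRFDSLGGGSFLGGKRSGDSIGGGNFLGGKRADSLGG
GSALGGKRRSFVDSLGGGDSPFA*
>FLGa_B signal_end=15 is_partial=no synthetic=yes
MKWLVLFAVLAVSSAGAESGEAHVFDSLGGGHVPYYKRGTDSGDGHVFDTLGGGHVPYYK
RFDSLGGGSFLGGKRFDSLGGGSFLGGKRFDSLGGGSFLGGKRFDSLGGGSFLGGKRFDS
LGGGSFLGGKRFDSLGGGSFLGGKRFDSLGGGSFLGGKRFDSLGGGSFLGGKRSGDSIGG
GNFLGGKRADSLGGGSALGGKRRSFVDSLGGGDSPFA*
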