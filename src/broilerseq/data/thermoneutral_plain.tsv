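# Reference sweep table: broilers in a non-enriched pen at thermoneutral temperature
# (assessment day 21, n = 10 broilers). Verbatim transcription of the published table.
# Columns: comma-joined MinSupport levels <TAB> reported patterns ("; "-separated) or None.
1.0,0.9,0.8	<{Ld,P}> (n = 10)
0.7,0.6	<{Ld,F}> (n = 7); <{Ld,P} {Ld,P}> (n = 7)
0.5	<{Ld,F} {Ld,P}> (n = 5)
0.4	<{Ld,P} {Ld,F}> (n = 4)
0.3	<{P,F,P}> (n = 3); <{Ld,P,F}> (n = 3); <{Ld,P} {Ld,P} {Ld,P}> (n = 3)
0.2	<{E,W,F}> (n = 2); <{W,F,P}> (n = 2); <{D,W,E}> (n = 2); <{F,P,W,E}> (n = 2); <{Ld,P} {Ld,P,F}> (n = 2); <{Ld,P} {D,W,E}> (n = 2); <{P,F,P} {Ld,P}> (n = 2); <{P,F,P} {Ld,F}> (n = 2); <{Ld,F} {Ld,P,F}> (n = 2); <{Ld,F} {D,W,E}> (n = 2); <{Ld,P,F} {Ld,P}> (n = 2); <{W,F,P} {Ld,P}> (n = 2); <{Ld,P} {Ld,P} {Ld,F}> (n = 2); <{Ld,P} {Ld,F} {Ld,P}> (n = 2); <{P,F,P} {Ld,P} {Ld,P}> (n = 2); <{P,F,P} {Ld,P} {Ld,F}> (n = 2); <{Ld,F} {Ld,P} {Ld,P}> (n = 2); <{Ld,F} {Ld,P} {Ld,P,F}> (n = 2); <{P,F,P} {Ld,P} {Ld,F} {Ld,P}> (n = 2)
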