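# Reference sweep table: broilers in an enriched pen under heat stress (30 C)
# (assessment day 22, n = 10 broilers). Verbatim transcription of the published table.
# Columns: comma-joined MinSupport levels <TAB> reported patterns ("; "-separated) or None.
1.0,0.9,0.8,0.7,0.6,0.5,0.4	None
0.3	<{E,W,F}> (n = 3)
0.2	<{Ld,F}> (n = 2); <{Ld,W,D}> (n = 2); <{Ld,P,W,P}> (n = 2); <{E,W,D}> (n = 2); <{P,F,St,P}> (n = 2); <{E,F,E}> (n = 2); <{P,F,St,P} {E,W,F}> (n = 2)
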