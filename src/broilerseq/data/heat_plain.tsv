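# Reference sweep table: broilers in a non-enriched pen under heat stress (30 C)
# (assessment day 22, n = 10 broilers). Verbatim transcription of the published table.
# Columns: comma-joined MinSupport levels <TAB> reported patterns ("; "-separated) or None.
1.0,0.9,0.8,0.7,0.6,0.5	None
0.4	<{Ld,P,W,D,W}> (n = 4)
0.3	<{Ld,P}> (n = 3); <{Ld,F,P}> (n = 3)
0.2	<{Ld,P,F}> (n = 2); <{Ld,P,St,Ll}> (n = 2); <{E,W,P,W,F}> (n = 2); <{Ld,P,St,Ll} {Ld,P,W,D,W}> (n = 2)
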