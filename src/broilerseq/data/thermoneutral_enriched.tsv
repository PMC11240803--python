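# Reference sweep table: broilers in an enriched pen at thermoneutral temperature
# (assessment day 21, n = 10 broilers). Verbatim transcription of the published table;
# two entries at level 0.2 were printed without an "(n = k)" count and are kept that way.
# Columns: comma-joined MinSupport levels <TAB> reported patterns ("; "-separated) or None.
1.0,0.9,0.8	None
0.7,0.6	<{Ld,P}> (n = 7)
0.5	<{Ld,P,F,P}> (n = 5); <{Ld,P,F}> (n = 5)
0.4	<{F,P}> (n = 4)
0.3	<{P,F,P}> (n = 3); <{P,Ld}> (n = 3); <{Ld,F,P}> (n = 3); <{Ld,P} {Ld,P,F,P}> (n = 3); <{Ld,P,F,P} {Ld,P,F,P}> (n = 3)
0.2	<{Ld,F,P,F}> (n = 2); <{Ld,F}> (n = 2); <{Ld,P,Sf,P}> (n = 2); <{E,W,F}> (n = 2); <{Ld,P} {Ld,F}> (n = 2); <{Ld,P} {Ld,F,P}> (n = 2); <{F,P} {Ld,P,F,P}> (n = 2); <{Ld,P,F,P} {Ld,F}> (n = 2); <{P,F,P} {Ld,P}> (n = 2); <{P,F,P} {Ld,P,F,P}> (n = 2); <{Ld,F} {Ld,F}> (n = 2); <{P,Ld} {Ld,P}>; <{P,Ld} {Ld, P,F}>; <{E,W,F} {F,P}> (n = 2); <{Ld,P,F} {Ld,P}> (n = 2); <{Ld,P} {Ld,F} {Ld,F}> (n = 2); <{Ld,P} {Ld,P,F,P} {Ld,P,F,P}> (n = 2); <{Ld,P} {Ld,P,F,P} {Ld,F}> (n = 2); <{Ld,P,F,P} {Ld,F} {Ld,F}> (n = 2); <{Ld,P} {Ld,P,F,P} {Ld,F} {Ld,F}> (n = 2)
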