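# Conventional exon boundaries of the dystrophin (Dp427m) protein domains.
# Only the syntrophin-binding range (exons 71-74) is fixed by the clinical
# literature; the remaining boundaries follow common convention and may be
# edited freely.  Format: NAME=first-last (1-based exon indices, inclusive).
ABD=1-8
ROD=9-63
CYS_RICH=64-70
C_TERM=71-79
SYNTROPHIN_BINDING=71-74
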