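# Regulatory elements of the 50-kb Pou5f1 locus, mm10 (chr17:35,484,600-35,534,600)
# promoters given as +-300 bp around the annotated position
chr17	35485600	35486100	E1
chr17	35502100	35502700	E2
chr17	35505700	35506300	P1
chr17	35516500	35517100	P2
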