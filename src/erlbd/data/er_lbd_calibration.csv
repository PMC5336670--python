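label,similarity_pct,rmsd_A
Human,100,0
Rat,94,0.71
Oyster,72,1.45
Rotifer,68,
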