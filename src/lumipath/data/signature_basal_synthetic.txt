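# synthetic basal signature fixture (matches the simulator's marker panel)
Krt5
Krt14
Acta2
Myh11
Mylk
Cnn1
Trp63
Trp73
Oxtr
Myl9
Tagln
Sparc
Itga6
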