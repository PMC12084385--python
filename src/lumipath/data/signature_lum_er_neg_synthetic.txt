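# synthetic luminal ER-negative signature fixture
Elf5
Kit
Aldh1a3
Cd14
Krt8
Krt18
Krt19
Cldn3
Cldn4
Wfdc18
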