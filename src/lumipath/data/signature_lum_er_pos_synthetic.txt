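# synthetic luminal ER-positive signature fixture
Esr1
Pgr
Prlr
Cited1
Foxa1
Areg
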