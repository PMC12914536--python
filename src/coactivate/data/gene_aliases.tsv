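# alias	canonical (mouse Title-case; upper-cased automatically for human/pig/macaque)
Tmem173	Sting1
Mb21d1	Cgas
Figf	Vegfd
Pigf	Pgf
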