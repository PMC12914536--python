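EC	endothelial cells (literature-standard panel, not from any single source)	Pecam1	Cdh5	Cldn5	Egfl7
rod	rod photoreceptors	Rho	Nrl	Gnat1	Pde6b
cone	cone photoreceptors	Arr3	Gnat2	Opn1sw	Pde6h
microglia	microglia	Cx3cr1	P2ry12	Tmem119	Aif1
muller	Muller glia	Rlbp1	Glul	Slc1a3	Apoe
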