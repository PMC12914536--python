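cGAS-STING	cGAS-STING signaling pathway signature	Irf3	Tmem173	Stat1	Cxcl10	Ifi44	Ifih1	Irf7	Isg15	Rtp4	Ifit1	Ifit2	Ifit3	Oasl2	Ikbke	Ddx58	Cgas	Tbk1	Icam1	Nfkb1	Stat2
Angiogenesis	Angiogenesis signature	Mmp2	Vegfa	Vegfb	Vegfc	Vegfd	Pigf	Kdr	Flt1	Nrp1	Nrp2	Ang	Angpt2	Fgf1	Fgf2	Tek	Notch1	Pdgfb	Tgfbr1	Tgfb1	Acvrl1	Id1	Tgfbr3	Efnb2	Efna1	Ephb4	Ephb2	Epha4
Hallmark angiogenesis	MSigDB hallmark angiogenesis gene set	Apoh	App	Ccnd2	Col3a1	Col5a2	Cxcl5	Fgfr1	Fstl1	Itgav	Jag1	Jag2	Kcnj8	Lpl	Lrpap1	Lum	Msx1	Nrp1	Olr1	Pdgfa	Pf4	Pglyrp1	Postn	Prg2	Ptk2	S100a4	Serpina5	Slco2a1	Spp1	Stc1	Thbd	Timp1	Tnfrsf21	Vav2	Vcan	Vegfa	Vtn
Endothelial activation/proliferation	Angiogenic/tip-cell activation markers	Mki67	Cxcr4	Dll4	Aplnr	Esm1
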