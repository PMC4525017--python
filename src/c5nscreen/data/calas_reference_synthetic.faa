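>cALAS_ref_synthetic synthetic cyclizing ALAS reference protein, 400 aa
THGVDLWRARRLMGAILPGDDEPAVHDEVEIAWLVRGSIKDGVQGLSREEAQGYWGYLWI
TIPRWVHNVVWCSATTTSVMPLSADPGVAAAYDSISGVVHRRTVDRALVGDKRAPGLSSV
LVEHLLKMLNISGDTATYLPIITPPHRDLGGFSIDAMGTAELYTPRSAEKTITPGTRYSC
PLLKLVTQIPVRASSTLAGVFRLAEAPLGDESARETAARTALRRTYRDIVTSNSEVHAVG
MYIKDKQDRKSAADPGLAGEITPVLRQIRVIGAAILVRRRLELTGLDAENAREEPLTLTS
TALTLAVRTDGPWDAYGQGPPRVGDTRFFERVRPVPGTQEAEVFRTHDVAPHMDVLCIRY
DVSSSRGMSVLDGERYLGAPDYGELGILTAASLIGKAPRG
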