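system,form,refcode,quantity,value_kj_mol,provenance
o-acetamidobenzamide,alpha,ACBNZA01,E_inter,-146.9,printed
o-acetamidobenzamide,alpha,ACBNZA01,E_intra_global,15.0,printed (approximate; adjustment-dominated)
o-acetamidobenzamide,alpha,ACBNZA01,E_latt_global,-131.9,derived: -146.9 + 15.0
o-acetamidobenzamide,beta,ACBNZA02,E_inter,-205.3,printed
o-acetamidobenzamide,beta,ACBNZA02,E_latt_global,-134.4,derived: -131.9 - 2.5 (relative lattice energy of the pair)
o-acetamidobenzamide,beta,ACBNZA02,E_intra_global,70.9,derived: -134.4 - (-205.3); printed as approximately 71
ritonavir,I,YIGPIO02,E_latt_global,-291.0,printed (upper end of the stated range)
ritonavir,I,YIGPIO02,E_intra_global,102.0,printed (approximate)
ritonavir,I,YIGPIO02,E_inter,-393.0,derived: -291.0 - 102.0
ritonavir,II,YIGPIO03,E_latt_global,-297.0,printed (lower end of the stated range)
ritonavir,II,YIGPIO03,E_intra_global,129.0,printed (approximate)
ritonavir,II,YIGPIO03,E_inter,-426.0,derived: -297.0 - 129.0
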