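compound,refcode_ref,refcode_alt,dH_exp,dE_latt,subset,source_note
o-acetamidobenzamide,ACBNZA01,ACBNZA02,2.9,2.5,validation,experimental enthalpy difference from thermal analysis; alt refcode corrected from a typeset artifact
cimetidine,CIMETD01,CIMETD02,2.3,2.6,validation,
probucol,HAXHET,HAXHET01,2.1,1.0,validation,
bicalutamide,JAYCES,JAYCES02,4.7,-3.9,validation,computed order inverted relative to experiment
ritonavir,YIGPIO03,YIGPIO02,6.9,6.0,validation,reference YIGPIO03 is the stable form II; YIGPIO02 is form I
4-methyl-2-nitroacetanilide,MNIAAN11,MNIAAN12,2.4,5.6,validation,multi-form compound; both pairs share the reference form
4-methyl-2-nitroacetanilide,MNIAAN11,MNIAAN02,3.4,5.2,validation,
anthranilic acid,AMBACO06,AMBACO03,1.8,-0.6,test,computed order inverted relative to experiment
4-aminobenzoic acid,AMBNAC04,AMBNAC06,2.8,0.1,test,
benzophenone,BPHENO12,BPHENO11,4.1,2.2,test,
4'-hydroxyacetophenone,HACTPH30,HACTPH31,0.5,4.1,test,
metacetamol,MENSEE01,MENSEE04,4.7,5.8,test,
picolinamide,PICAMD04,PICAMD03,1.1,2.0,test,
sulfamerazine,SLFNMA01,SLFNMA02,3.5,6.4,test,
phenylpiracetam,SANBAN,SAMZOY,2.7,-0.7,test,computed order inverted relative to experiment
carbamazepine,CBMZPN10,CBMZPN11,1.3,3.3,test,multi-form compound; both pairs share the reference form
carbamazepine,CBMZPN10,CBMZPN12,1.9,-0.3,test,computed order inverted relative to experiment
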