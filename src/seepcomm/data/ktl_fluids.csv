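site,sampled,temperature:C,pH,Cl:mM,Br:uM,sulfate:uM,nitrate:mM,ammonium:mM,sulfide:uM,DOC:mM,Na:mM,Ca:mM,K:mM,Mg:mM,Sr:uM,ratio_87_86,TOC:wt_pct
KTLS,2006-12,56.3,7.5,62.0,122.1,600.4,BDL,0.83,BDL,NA,65.3,0.36,4.00,0.40,12.3,0.71056,0.64
KTL01,2006-12,55.3,8.1,55.3,119.9,155.1,BDL,0.37,BDL,3.6,78.2,0.13,5.19,0.34,13.1,0.71128,0.54
KTL01,2007-05,53.3,8.0,69.8,141.7,225.3,BDL,0.36,BDL,3.5,76.7,0.19,6.10,0.32,12.8,NA,1.02
KTL02,2007-05,77.9,7.5,83.1,179.8,80.9,BDL,0.04,BDL,NA,97.2,0.09,4.80,0.23,27.8,0.71142,0.72
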