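panel,label,terms,k,aicc,delta_aicc_printed,weight_printed
core,~ NULL,,3,96.47,0.00,0.43
core,~ maturity stage,maturity,4,97.10,0.63,0.31
core,~ spawn,spawn,4,98.45,1.99,0.16
core,~ maturity stage + spawn,maturity+spawn,5,99.31,2.84,0.10
home,~ maturity stage,maturity,4,75.37,0.00,0.49
home,~ NULL,,3,76.52,1.15,0.28
home,~ maturity stage + spawn,maturity+spawn,5,77.84,2.47,0.14
home,~ spawn,spawn,4,78.76,3.39,0.09
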