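symbol,name,unit,center,step
X1,temperature,degC,50,10
X2,ethanol,percent,75,10
X3,ls_ratio,mL/g,30,10
X4,power,W,120,15
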