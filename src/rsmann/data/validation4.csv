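run,temperature,ethanol,ls_ratio,power,yield,yield_sd,rsm_pred,rsm_dev,ann_pred,ann_dev
1,60,65,30,120,39.65,0.97,40.02,0.37,39.98,0.33
2,50,75,20,135,34.45,2.17,35.96,1.51,33.29,1.16
3,60,75,30,135,37.70,3.13,39.77,2.07,36.69,1.01
4,50,65,20,120,33.70,2.55,33.08,0.62,33.82,0.12
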