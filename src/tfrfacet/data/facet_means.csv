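food_code,group,mean_g,sd_g,max_g,q90_g
O010301,rice,176.53,62.41,694.10,258.13
O010301,other,92.35,54.22,676.29,160.34
O010302,rice,77.23,25.17,216.67,110.02
O010302,other,100.13,29.75,291.05,138.95
O010303,rice,461.07,238.07,2309.01,764.92
O010303,other,790.04,433.96,3879.03,1340.42
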