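food_code,stratum,cr_g_per_day
O010301,male,158.48
O010301,female,93.63
O010301,mean,127.5
O010302,male,204.49
O010302,female,124.64
O010302,mean,177.87
O010303,male,181.86
O010303,female,195.81
O010303,mean,188.06
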