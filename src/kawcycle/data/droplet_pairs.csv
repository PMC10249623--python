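compound,log_k_true,log_k_apparent
4:2 FTI,4.93,4.13
6:1 FTI,5.66,4.34
6:1 FTI-7H,4.62,4.06
6:2 FTAC,5.43,4.22
4:2 FTMAC,4.65,4.02
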