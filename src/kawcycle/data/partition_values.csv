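compound,quantity,method,log_k,ci_low,ci_high
3:1 FTOH,hxd/w,modified_vprhs,-0.35,-0.37,-0.32
3:1 FTOH,aw,cycle,-1.89,,
3:1 FTOH,aw,standard_vprhs,-2.03,,
3:3 FTOH,hxd/w,batch,0.52,0.51,0.54
3:3 FTOH,hxd/w,modified_vprhs,0.32,0.17,0.47
3:3 FTOH,aw,cycle,-2.17,,
3:3 FTOH,aw,standard_vprhs,-2.04,,
4:2 FTOH,hxd/w,batch,0.79,0.77,0.81
4:2 FTOH,hxd/w,modified_vprhs,0.75,0.70,0.80
4:2 FTOH,aw,cycle,-1.57,,
4:2 FTOH,aw,standard_vprhs,-1.56,,
4:4 FTOH,hxd/w,batch,1.60,1.58,1.62
4:4 FTOH,hxd/w,modified_vprhs,1.43,1.09,1.71
4:4 FTOH,aw,cycle,-1.97,,
4:4 FTOH,aw,standard_vprhs,-1.28,,
6:2 FTOH,hxd/w,batch,2.50,2.42,2.59
6:2 FTOH,hxd/w,shared_headspace,2.51,2.44,2.58
6:2 FTOH,aw,cycle,-0.64,,
7:1 FTOH,hxd/w,shared_headspace,2.70,2.56,2.84
7:1 FTOH,aw,cycle,-0.26,,
8:2 FTOH,hxd/w,shared_headspace,3.75,3.73,3.78
8:2 FTOH,aw,cycle,0.11,,
5:2s FTOH,hxd/w,batch,2.00,1.93,2.08
5:2s FTOH,hxd/w,shared_headspace,2.04,1.98,2.11
5:2s FTOH,hxd/w,modified_vprhs,1.55,1.18,1.75
5:2s FTOH,aw,cycle,-0.15,,
4:2 FTI,hxd/w,batch,4.13,3.89,4.36
4:2 FTI,hxd/w,shared_headspace,4.93,4.86,4.99
4:2 FTI,aw,cycle,1.60,,
6:1 FTI,hxd/w,batch,4.34,3.82,4.86
6:1 FTI,hxd/w,shared_headspace,5.66,5.36,5.95
6:1 FTI,aw,cycle,2.28,,
6:1 FTI-7H,hxd/w,batch,4.06,3.72,4.39
6:1 FTI-7H,hxd/w,shared_headspace,4.62,4.55,4.70
6:1 FTI-7H,aw,cycle,0.70,,
6:2 FTAC,hxd/w,batch,4.22,3.92,4.51
6:2 FTAC,hxd/w,shared_headspace,5.43,5.40,5.46
6:2 FTAC,aw,cycle,1.27,,
4:2 FTMAC,hxd/w,batch,4.02,3.82,4.21
4:2 FTMAC,hxd/w,shared_headspace,4.65,4.58,4.72
4:2 FTMAC,aw,cycle,0.62,,
4:2 FTMAC,aw,standard_vprhs,-0.14,,
PFBSA,hxd/w,batch,-1.15,-1.20,-1.10
PFBSA,aw,cycle,-4.89,,
PFHxSA,hxd/w,batch,0.39,0.28,0.51
PFHxSA,aw,cycle,-3.94,,
PFOSA,hxd/w,batch,1.80,1.72,1.87
PFOSA,aw,cycle,-3.04,,
MeFBSA,hxd/w,batch,0.82,0.80,0.85
MeFBSA,aw,cycle,-2.85,,
MeFHxSA,hxd/w,batch,2.25,2.16,2.34
MeFHxSA,aw,cycle,-2.01,,
EtFHxSA,hxd/w,batch,2.95,2.85,3.04
EtFHxSA,aw,cycle,-1.58,,
MeFBSE,hxd/w,batch,0.49,0.45,0.52
MeFBSE,aw,cycle,-4.35,,
EtFHxSE,hxd/w,batch,2.76,2.66,2.87
EtFHxSE,aw,cycle,-3.02,,
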