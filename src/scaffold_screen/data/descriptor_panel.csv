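compound_id,name,mw,alogp,hba,hbd,psa,qed,logbb_cl,logbb_ri,logbb_exp
4,menadione,253.25,0.98,4,0,88.18,0.76,-1.02,-0.57,
6,camphotamide,231.29,1.14,3,0,71.11,0.69,-0.74,-0.37,
14,tramiprosate,138.17,-0.91,3,1,80.06,0.58,-1.18,-0.78,
donepezil,donepezil,379.5,4.36,4,0,38.77,0.72,0.23,0.45,0.89
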