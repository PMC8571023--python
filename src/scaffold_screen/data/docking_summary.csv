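compound_id,dg_bind,cl_rms,cl_rms_a,n_atm,n_tor,ki_printed,ki_unit,le_printed,tanimoto
1,-3.05,,,12,6,5.7,mM,-0.25,0.57
2,-3.7,,,11,5,1.89,mM,-0.34,0.67
3,-5.15,0.21,0.74,13,5,162.66,uM,-0.39,0.71
4,-7.11,0.29,0.54,18,2,5.87,uM,-0.39,0.56
5,-4.97,1.84,1.84,29,19,220.65,uM,-0.17,0.63
6,-6.82,0.04,0.07,15,1,9.61,uM,-0.46,0.5
7,-4.26,,,37,12,734.58,uM,-0.12,0.56
8,-6.17,1.78,1.18,40,10,28.9,uM,-0.15,0.45
9,-5.91,,,41,10,44.89,uM,-0.14,0.33
10,-2.97,,,52,15,6.53,mM,-0.06,0.27
11,0.66,,,61,30,3.06,M,0.01,0.44
12,-3.81,,,57,20,1.57,mM,-0.07,0.44
13,-5.71,,,55,16,62.99,uM,-0.1,0.42
14,-6.19,0.87,0.58,11,5,27.94,uM,-0.56,0.67
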