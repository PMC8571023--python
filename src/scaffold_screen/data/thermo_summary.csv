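compound_id,name,dg_pb,dg_gb,dg_pr,gscore,tds,dh_pb,dh_gb,bsa
4,menadione,-13.75,-19.71,-38.81,-6.51,-20.4,-34.15,-40.11,489.77
6,camphotamide,-15.61,-14.86,-21.36,-5.08,-17.86,-33.47,-32.72,481.09
14,tramiprosate,-2.28,-10.1,-16.31,-4.49,-17.91,-20.19,-28.01,373.56
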