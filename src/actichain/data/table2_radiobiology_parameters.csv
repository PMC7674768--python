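parameter,value,units,note
alpha_beta,3,Gy,xerostomia endpoint
mu,0.46,1/h,sublethal damage repair rate
injected_activity,100,kBq/kg,reference injection per body weight
rbe_exp,5,dimensionless,experimental high-LET RBE
d_ref,2,Gy,reference low-LET fraction dose
td50,14,Gy_EQD2,LKB 50% complication dose
m,0.88,dimensionless,LKB slope
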