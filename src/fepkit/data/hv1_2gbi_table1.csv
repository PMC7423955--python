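mutation,ddg_expt_kcal_mol,err_expt_kcal_mol,ddg_gbi1_kcal_mol,err_gbi1_kcal_mol,ddg_gbi2_kcal_mol,err_gbi2_kcal_mol,direction
D112E,1.01,0.05,4.9,0.7,2.3,0.7,forward
V178A,-0.56,0.05,0.8,0.3,0.8,0.3,forward
S181A,0.24,0.05,1.1,0.3,1.1,0.3,forward
V109A,-0.26,0.06,0.0,0.3,-0.4,0.3,forward
R208K,-0.01,0.05,6.8,0.8,1.7,0.8,forward
R211S,0.11,0.05,-6.3,0.7,-7.1,0.7,forward
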