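system_label,correction_kcal_mol
R211S:apo,-3.1042
R211S:holo_gbi1,-3.1030
R211S:holo_gbi2,-3.1019
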