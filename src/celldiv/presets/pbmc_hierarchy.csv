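fine,coarse
CD4_T,Lymphoid
CD8_T,Lymphoid
MAIT,Lymphoid
gdT,Lymphoid
NK,Lymphoid
B_naive,Lymphoid
B_memory,Lymphoid
Plasma,Lymphoid
CD14_Mono,Myeloid
CD16_Mono,Myeloid
cDC,Myeloid
pDC,Myeloid
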