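cell_type,quantity,bin,d_lo_um,d_hi_um,per_um_edge
fibroblast,barbed_ends,1,0.0,0.25,145
fibroblast,barbed_ends,2,0.25,0.5,42.5
fibroblast,branches,1,0.0,0.25,37.5
fibroblast,branches,2,0.25,0.5,37.5
fibroblast,filaments,1,0.0,0.25,150
fibroblast,filaments,2,0.25,0.5,130
keratocyte,barbed_ends,1,0.0,0.212,309
keratocyte,barbed_ends,2,0.212,0.424,238
keratocyte,pointed_ends,1,0.0,0.212,91
keratocyte,pointed_ends,2,0.212,0.424,231
keratocyte,filaments,1,0.0,0.106,200
keratocyte,filaments,2,0.106,0.212,256
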