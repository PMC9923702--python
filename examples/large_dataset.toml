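# Overrides in the spirit of a large (~4000 cells x ~13000 genes) dataset:
# bigger classification neighbourhood, wider alignment range, and a PCA
# pre-reduction before the diffusion map.
k = 1000
kmax = 400
pca_predim = 300
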