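# Image BSS demo on synthetic textures (uniform prior, family-default
# smoothing). Scaled schedule: 1e7 pixel presentations at tau_W = 5e3.
experiment: images
rule: eghr
prior: {family: uniform}
seed: 0
extra: {n_images: 4, shape: [64, 64], n_steps: 10000000, tau_W: 5000}
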