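# Undercomplete: 32 neurons, 2 Laplace sources, stacked-rotation mixing.
# Window-averaged updates and a slow learning time constant keep the
# 32-output gate noise below the 5-degree alignment criterion.
experiment: train
rule: eghr
source: {family: laplace, M: 2, temporal: iid}
prior: {family: laplace, gamma: 1000}
mixing: {kind: stacked_rotation, N: 32}
schedule: {T: 20000000, dt_update: 100, batch: 100, tau_W: 100000, checkpoint_every: 1000}
seed: 0
extra: {init: unit_circle_K}
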