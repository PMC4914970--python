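# Non-rotation mixing, uniform sources; MI of the outputs tracked over learning.
experiment: train
rule: eghr
source: {family: uniform, M: 2, temporal: langevin, tau_s: 50, dt: 1}
prior: {family: uniform, gamma: 100}
mixing: {kind: explicit, A: [[1.0, 0.5], [0.5, 1.0]]}
schedule: {T: 2000000, dt_update: 100, tau_W: 1000, checkpoint_every: 200}
W0: [[-2.2, 0.0], [0.0, -2.2]]
seed: 0
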