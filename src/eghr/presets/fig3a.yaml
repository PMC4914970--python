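# Rotation mixing (pi/6), Laplace sources, common start W0 = -1.5 I.
experiment: train
rule: eghr
source: {family: laplace, M: 2, temporal: langevin, tau_s: 50, dt: 1}
prior: {family: laplace, gamma: 100}
mixing: {kind: rotation, theta: pi/6}
schedule: {T: 2000000, dt_update: 100, tau_W: 1000, checkpoint_every: 200}
W0: [[-1.5, 0.0], [0.0, -1.5]]
seed: 0
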