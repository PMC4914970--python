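# Velocity map of the EGHR on the rotation manifold (Laplace prior, pi/6 mixing).
experiment: velocity_map
rule: eghr
source: {family: laplace, M: 2}
prior: {family: laplace, gamma: 100}
mixing: {kind: rotation, theta: pi/6}
seed: 0
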