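# Study setting: sidak procedure, N=64, m=2 endpoints, eta = 0.1 * 0.711
N: 64
m: 2
alpha: 0.05
nu: 0.1
effect_size: 0.711
procedure: sidak
r: 100000
seed: 20240930
rps:
  - {name: CR}
  - {name: BSD, b: 3}
  - {name: MP, b: 3}
  - {name: PBR, block_size: 4}
  - {name: RAR}
  - {name: EBC, p: 0.67}
  - {name: CHEN, p: 0.67, b: 2}
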