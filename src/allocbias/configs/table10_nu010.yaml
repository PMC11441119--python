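# Worked example: hypothetical single-center trial in Tuberous sclerosis
# complex planning 5 correlated BSID developmental scales (cognitive,
# language, motor, adaptive behavior, social-emotional) as multiple primary
# endpoints, with pooled standard deviations, effect sizes and the
# correlation matrix estimated from a published trial in the same disease.
# Bias effects are 10% of the per-endpoint effect sizes.
N: 24
m: 5
alpha: 0.05
sigma: [15.70, 14.19, 15.02, 21.37, 22.71]
corr:
  - [1.00, 0.79, 0.86, 0.22, 0.48]
  - [0.79, 1.00, 0.77, 0.30, 0.57]
  - [0.86, 0.77, 1.00, 0.15, 0.46]
  - [0.22, 0.30, 0.15, 1.00, 0.46]
  - [0.48, 0.57, 0.46, 0.46, 1.00]
nu: 0.1
effect_sizes: [0.114, 0.509, 0.315, 0.361, 1.034]
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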