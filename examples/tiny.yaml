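# Desk-scale training configuration for the 64x64 synthetic dataset.
learning_rate: 0.0003
eps: 1.0e-08
batch_size: 8
epochs: 40
input_size: 64
channels: 1
patch_size: 16
dim: 64
depth: 3
heads: 4
num_classes: 3
ats_tokens:
- 16
- 8
- 4
split_ratios:
- 0.7
- 0.1
- 0.2
labeled_fraction: 0.8
seed: 0
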