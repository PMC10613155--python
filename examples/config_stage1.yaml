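# Stage-1 hypertension on a coarse FEM ventricle: 120 -> 140 mmHg at day 0.
model: fem
gain_times_T: 0.1
baseline_pressure: 120.0
steps: [[0.0, 140.0]]
horizon: 2000.0
dt: 2.5
target_elements: 1500
order: 1
eps_pre_mm: 0.01
settle_steps: 100
output_dir: scratch/stage1
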