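# Full-scale study configuration: the split sizes mirror the study design
# (70-sample few-shot set, 300-sample references, long-tailed test set of
# 2035 records, 16,304-record unlabeled pool).  Intended for a long offline
# run; use configs/tiny.yaml for a desk-scale pass.
seed: 0
run_dir: scratch/run_default

splits:
  few_shot_n_per_class: 14        # N = 70 labeled samples
  reference_n: 300
  val_n_per_class: 7
  test_size: 2035
  test_mixture: [0.55, 0.15, 0.12, 0.10, 0.08]
  unlabeled_n: 16304

augment:
  ssl_views:
    crop_frac_range: [0.7, 1.0]
    scale_range: [0.8, 1.2]
    noise_sd: 0.05
  downstream_strong:
    crop_frac_range: [0.5, 1.0]
    scale_range: [0.5, 1.5]
    noise_sd: 0.15

encoder:
  preset: default                 # 3 conv blocks + 2 attention blocks, ~77k params

pretrain:
  batch_pairs: 64
  temperature: 0.1
  epochs: 50
  learning_rate: 1.0e-3

finetune:
  learning_rate: 1.0e-4           # low rate limits representation drift
  max_epochs: 100
  patience: 10
  batch_size: 32

audit:
  groups: ["A", "A'", "B", "C", "E", "D-Aug", "D-NoAug"]
  n_seeds: 3
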