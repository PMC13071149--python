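# Desk-scale configuration: same study structure (70-sample few-shot set,
# 300-sample references, all seven groups) with a 64-record unlabeled pool,
# a shorter test set, the small encoder preset and a 30-epoch budget, so the
# whole matrix runs in minutes on one CPU.
seed: 0
run_dir: scratch/run_tiny

splits:
  few_shot_n_per_class: 14        # N = 70, unchanged from the study design
  reference_n: 300
  val_n_per_class: 7
  test_size: 200
  test_mixture: [0.55, 0.15, 0.12, 0.10, 0.08]
  unlabeled_n: 64

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
  preset: tiny                    # ~30k parameters

pretrain:
  batch_pairs: 32
  temperature: 0.1
  epochs: 30
  learning_rate: 1.0e-3

finetune:
  learning_rate: 1.0e-4
  max_epochs: 30
  patience: 10
  batch_size: 32

audit:
  groups: ["A", "A'", "B", "C", "E", "D-Aug", "D-NoAug"]
  n_seeds: 5
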