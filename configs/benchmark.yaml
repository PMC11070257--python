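# Pipeline configuration for the synthetic 3-class benchmark.
#
# Every pipeline constant is a default that can be overridden here: the class
# map (with merges, the background tag, per-class focal segment advances and
# centralization-penalty flags), signal conditioning, augmentation
# probabilities/ranges, architecture and training schedule. A deployment
# configuration for a real assemblage uses the same schema with its own class
# list (e.g. 30 species classes after merges + a bat class + a catch-all
# reject class) and per-species advances.

classes:
  names: [pulser_slow, pulser_fast, sweeper_high]
  merges: {}            # e.g. {"speciesB_synonym": "speciesB"}
  background_tag: background
  reject_class: null    # e.g. "reject" for a catch-all class
  penalty_classes: [pulser_slow, pulser_fast, sweeper_high]
  focal_advance: {}     # per-class values from {0.05, 0.15, 0.2, 0.4, 0.55, 0.6}
  default_focal_advance: 0.2

signal:
  target_rate: 96000
  highpass_cutoff_hz: 6900.0
  highpass_order: 12
  segment_length_s: 0.8
  inference_advance_s: 0.2

detection:
  threshold: 0.5
  sweep_step: 0.05
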