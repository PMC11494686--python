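# Desk-scale default pipeline configuration.
#
# The synthetic cohort emulates the study conditions: 23 participants, three
# episodic-memory tasks, one 696-sample acquisition per task at TR = 0.8 s.
# The parcellation is reduced to the a-priori ROI labels plus the early- and
# ventrolateral-visual regions they are contrasted against (38 label pairs,
# 76 regions), which keeps a full simulate -> report run at desk scale while
# preserving hemisphere pairing.  Injected effects mirror the qualitative
# task / ROI / phase / hemisphere selectivity the contrast battery probes.

seed: 7
out_dir: hopfec_out
log_level: INFO

acquisition:
  tr: 0.8
  n_samples: 696

bands:
  activation: {low: 0.05, high: 0.15, order: 2}
  fc: {low: 0.008, high: 0.08, order: 2}

hopf:
  a: -0.02
  f_hz: 0.05
  G: 1.0
  sigma: 0.01
  dt: 0.1
  burn_in: 60.0

gec:
  tau_seconds: 2.0
  epsilon: 0.0005
  max_iter: 200
  patience: 10
  clip_min: 0.0
  clip_max: 0.2
  reverse_for_fmri: true
  hemisphere: L

cohort:
  n_participants: 23
  tasks: [object_location, reward_location, word_pair]
  base_labels: [VMV1, VMV2, VMV3, VVC, PHA1, PHA2, PHA3,
                STGa, STSda, STSdp, STSvp, TGd, TGv, PSL,
                "44", "45", 47l,
                d32, p24, pOFC, s32, 10d, 10pp, 11l, a10p, OFC, p10p,
                LIPv, MIP, VIP,
                V1, V2, V3, V4, FFC, PIT, V8, TE2p]
  density: 0.15
  strength_scale: 0.1
  network_seed: 7
  subject_gain_jitter_sd: 0.2
  subject_coupling_jitter_sd: 0.1
  effects:
    - {roi: scene, task: object_location, phase: both, hemisphere: both, gain: 1.5}
    - {roi: scene, task: reward_location, phase: both, hemisphere: both, gain: 1.5}
    - {roi: scene, task: object_location, phase: both, hemisphere: R, gain: 0.4}
    - {roi: reward, task: reward_location, phase: storage, hemisphere: both, gain: 1.2}
    - {roi: semantic, task: word_pair, phase: storage, hemisphere: both, gain: 1.2}
    - {roi: broca, task: word_pair, phase: storage, hemisphere: both, gain: 0.8}
    - {roi: broca, task: word_pair, phase: storage, hemisphere: L, gain: 0.6}
    - {roi: intraparietal, task: object_location, phase: both, hemisphere: both, gain: 1.0}
    - {roi: intraparietal, task: reward_location, phase: both, hemisphere: both, gain: 1.0}

battery:
  alpha: 0.02
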