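# Default TBP/TATA-box affinity model.
#
# The PWM is given as per-position base frequencies (order A, C, G, T) and
# converted to natural-log odds against a uniform background at load time.
# Information is concentrated in the 7-bp TATAAAA core (positions 2-8);
# the flanks are weakly G/C-biased, matching the GC-rich context of human
# core promoters.  Consensus: GTATAAAAGGGGGGG.
#
# The dinucleotide tables are relative scales of duplex-step deformability
# (slide) and bending propensity (bend).  Both are dominated by the TA and
# AT steps at which TBP kinks the duplex, with AA/TT and the flexible
# CA/TG steps intermediate; they are symmetric under strand reversal of
# the step (AA=TT, CA=TG).
#
# Calibration maps each raw step score linearly onto the -ln(K_D) scale
# (K_D molar) by anchoring the consensus window at 20.7 (K_D = 1 nM, a
# strong TATA box) and a poly-G window at 13.8 (K_D = 1 uM, nonspecific
# DNA binding).

pwm:
  frequencies:
    - [0.18, 0.28, 0.36, 0.18]
    - [0.05, 0.03, 0.02, 0.90]
    - [0.92, 0.02, 0.02, 0.04]
    - [0.03, 0.02, 0.02, 0.93]
    - [0.93, 0.02, 0.02, 0.03]
    - [0.65, 0.02, 0.03, 0.30]
    - [0.92, 0.02, 0.02, 0.04]
    - [0.55, 0.05, 0.08, 0.32]
    - [0.18, 0.28, 0.36, 0.18]
    - [0.18, 0.28, 0.36, 0.18]
    - [0.18, 0.28, 0.36, 0.18]
    - [0.18, 0.28, 0.36, 0.18]
    - [0.18, 0.28, 0.36, 0.18]
    - [0.18, 0.28, 0.36, 0.18]
    - [0.18, 0.28, 0.36, 0.18]

slide_property:
  AA: 0.35
  AC: 0.05
  AG: 0.05
  AT: 0.70
  CA: 0.25
  CC: 0.05
  CG: 0.05
  CT: 0.05
  GA: 0.05
  GC: 0.05
  GG: 0.05
  GT: 0.05
  TA: 1.00
  TC: 0.05
  TG: 0.25
  TT: 0.35

bend_property:
  AA: 0.50
  AC: 0.10
  AG: 0.10
  AT: 0.80
  CA: 0.45
  CC: 0.10
  CG: 0.10
  CT: 0.10
  GA: 0.10
  GC: 0.15
  GG: 0.10
  GT: 0.10
  TA: 1.00
  TC: 0.10
  TG: 0.45
  TT: 0.50

calibration:
  anchor_high: 20.7
  anchor_low: 13.8

significance_alpha_threshold: 0.95
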