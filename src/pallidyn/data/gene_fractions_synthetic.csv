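# Synthetic calibration fractions: per-gene target fractions of tonic / irregular /
# bursting discharge and of any-band oscillatory neurons. These are NOT published
# numbers; they were constructed to satisfy the cohort's reported constraints:
# tonic-rich AOPEP/PANK2/THAP1 (tonicity >= 33.4%); irregular >= 50% for AOPEP,
# TOR1A, VPS16, SGCE, PLA2G6; bursting > 30% for GNAL, SGCE, PLA2G6, KMT2B with
# the published requirement that this block is *significantly* more bursty than
# every remaining gene (so the two blocks are separated well beyond sampling and
# classification noise at cohort scale); oscillatory 84% for GNAL and 81.7% for
# PLA2G6; roughly half of AOPEP/PANK2 oscillatory; SGCE least tonic.
# Discharge fractions sum to 1 per gene.
gene,frac_tonic,frac_irregular,frac_bursting,frac_oscillatory
AOPEP,0.45,0.50,0.05,0.50
GNAL,0.15,0.40,0.45,0.84
KMT2B,0.20,0.40,0.40,0.75
PANK2,0.50,0.42,0.08,0.50
PLA2G6,0.08,0.50,0.42,0.817
SGCE,0.06,0.52,0.42,0.75
THAP1,0.45,0.43,0.12,0.65
TOR1A,0.20,0.65,0.15,0.70
VPS16,0.20,0.65,0.15,0.70
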