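# Species parameters for the raisin moth, Cadra figulilella.
# Temperature thresholds (°C)
DV0 = 13
DV1 = 15
DV2 = 30
DV3 = 36
# Soil-moisture thresholds (fraction of holding capacity)
SM0 = 0.25
SM1 = 0.8
SM2 = 1.5
SM3 = 2.5
# Cold stress
TTCS = 0
THCS = -0.001
# Heat stress
TTHS = 36
THHS = 0.0001
# Dry stress
SMDS = 0.02
HDS = -0.05
# Wet stress
SMWS = 2.5
HWS = 0.0015
# Hot-wet interaction stress
TTHW = 23
MTHW = 1.35
PHW = 0.075
# Degree-days above DV0 per generation
PDD = 292
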