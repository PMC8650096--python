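# Factor levels of the device design study.
# Flow rates in ml/h; lengths in micrometres; porosity dimensionless.
# wl/hl level 0.1 um is the "closed left connector" sentinel (SSC topology).
q1: [0.01, 0.02]
q2: [0.01, 0.02]
wl: [0.1, 20, 30, 40, 60]
wr: [20, 30, 40, 60]
hl: [0.1, 20, 30, 40, 60]
hr: [20, 30, 40, 60]
radius: [80, 120, 160]
phi: [0.2, 0.5, 0.7, 0.9]
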