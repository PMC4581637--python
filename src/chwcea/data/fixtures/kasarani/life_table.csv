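group,remaining_le_years
stillbirth,55.284058
neonatal_under_1m,64.487384
child_1_59m,30.998913
maternal,57.673111
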