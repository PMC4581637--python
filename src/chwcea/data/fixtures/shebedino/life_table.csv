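group,remaining_le_years
stillbirth,61.763701
neonatal_under_1m,60.697236
child_1_59m,63.775307
maternal,0.0
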