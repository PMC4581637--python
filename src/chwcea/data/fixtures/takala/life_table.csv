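group,remaining_le_years
stillbirth,70.582681
neonatal_under_1m,70.607241
child_1_59m,70.349317
maternal,54.833131
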