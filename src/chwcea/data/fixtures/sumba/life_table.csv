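group,remaining_le_years
stillbirth,71.276248
neonatal_under_1m,70.883781
child_1_59m,46.899545
maternal,53.067641
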