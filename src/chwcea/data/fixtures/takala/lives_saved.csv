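group,lives_saved_national,per_100k
stillbirth,24.73,9.17
neonatal_under_1m,35.55,13.19
child_1_59m,-0.24,-0.09
maternal,5.31,1.97
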