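group,lives_saved_national,per_100k
stillbirth,0.41,8.22
neonatal_under_1m,0.74,14.88
child_1_59m,0.05,0.96
maternal,0.11,2.27
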