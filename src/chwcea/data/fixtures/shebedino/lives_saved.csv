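group,lives_saved_national,per_100k
stillbirth,5.40,1.94
neonatal_under_1m,4.21,1.52
child_1_59m,7.18,2.58
maternal,0.01,0.005
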