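group,lives_saved_national,per_100k
stillbirth,2.22,0.78
neonatal_under_1m,12.76,4.50
child_1_59m,-0.04,-0.01
maternal,1.44,0.51
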