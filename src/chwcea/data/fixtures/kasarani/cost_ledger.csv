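name,category,amount,is_training,annualized
Pre-service training,start_up,729,false,true
One-off incentives/starter kits,start_up,233,false,true
Equipment,start_up,25,false,true
Stationery (registers and books),direct_recurrent,1552,false,true
Supervisory visits,indirect_recurrent,186,false,true
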