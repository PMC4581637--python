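name,category,amount,is_training,annualized
Pre-service training,start_up,5383,false,true
One-off incentives/starter kits,start_up,11381,false,true
Construction of new health posts,start_up,668940,false,true
Equipment,start_up,12284,false,true
Annual salary of community-based practitioners,direct_recurrent,762248,false,true
In-service training,direct_recurrent,1484,false,true
Other monetary incentives and allowances,direct_recurrent,2334921,false,true
Stationery (registers and books),direct_recurrent,38579,false,true
Supervisory visits,indirect_recurrent,3460,false,true
Supervisory meetings,indirect_recurrent,10715,false,true
Total volunteer costs,volunteer,310521,false,true
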