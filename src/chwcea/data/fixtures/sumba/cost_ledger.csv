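name,category,amount,is_training,annualized
One-off incentives/starter kits,start_up,7390,false,true
Construction of new health posts,start_up,817593,false,true
Equipment,start_up,5213,false,true
Annual salary of community-based practitioners,direct_recurrent,323471,false,true
In-service training,direct_recurrent,35620,false,true
Other monetary incentives and allowances,direct_recurrent,254398,false,true
Stationery (registers and books),direct_recurrent,38579,false,true
Supervisory visits,indirect_recurrent,5964,false,true
Supervisory meetings,indirect_recurrent,259,false,true
Total volunteer costs,volunteer,21646,false,true
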