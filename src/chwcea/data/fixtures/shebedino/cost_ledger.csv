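name,category,amount,is_training,annualized
Pre-service training,start_up,8750.672,true,true
One-off incentives/starter kits,start_up,84,false,true
Construction of new health posts,start_up,83806,false,true
Equipment,start_up,15437,false,true
Annual salary of community-based practitioners,direct_recurrent,181094,false,true
In-service training,direct_recurrent,16303,false,true
Medicines,direct_recurrent,13413,false,true
Supervisory visits,indirect_recurrent,97409,false,true
Supervisory meetings,indirect_recurrent,7245,false,true
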