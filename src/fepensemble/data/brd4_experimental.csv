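transformation,exp,exp_bound,exp_sigma
L1->L3,1.26,False,
L3->L2,6.69,False,
L3->L4,0.00,False,
L4->L2,6.69,False,
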