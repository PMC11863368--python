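transformation,exp,exp_bound,exp_sigma
Ben->Phe,10.25,True,
Eth->Tol,1.00,False,
Tol->Ben,1.38,False,
Ide->Ido,1.00,False,
Ido->Bzf,-2.38,False,
Ide->Bzf,-1.38,False,
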