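transformation,condition,replicate,ddg_kjmol,sigma_kjmol
L1->L3,VIS,1,1.45,0.10
L1->L3,VIS,2,1.18,0.10
L1->L3,VIS,3,1.80,0.10
L1->L3,VIS,4,1.30,0.10
L1->L3,VIS,5,1.40,0.10
L3->L2,VIS,1,6.62,0.17
L3->L2,VIS,2,6.62,0.17
L3->L2,VIS,3,8.24,0.16
L3->L2,VIS,4,7.08,0.17
L3->L2,VIS,5,8.04,0.16
L3->L4,VIS,1,-0.38,0.08
L3->L4,VIS,2,-0.10,0.08
L3->L4,VIS,3,0.00,0.07
L3->L4,VIS,4,0.09,0.08
L3->L4,VIS,5,0.03,0.08
L4->L2,VIS,1,9.34,0.16
L4->L2,VIS,2,8.06,0.17
L4->L2,VIS,3,7.16,0.17
L4->L2,VIS,4,8.71,0.17
L4->L2,VIS,5,9.09,0.17
L1->L3,SIS,1,1.59,0.10
L1->L3,SIS,2,1.66,0.10
L1->L3,SIS,3,1.49,0.10
L1->L3,SIS,4,1.76,0.10
L1->L3,SIS,5,1.32,0.10
L3->L2,SIS,1,9.01,0.16
L3->L2,SIS,2,8.11,0.16
L3->L2,SIS,3,7.24,0.17
L3->L2,SIS,4,6.47,0.17
L3->L2,SIS,5,9.66,0.16
L3->L4,SIS,1,-0.30,0.08
L3->L4,SIS,2,-0.56,0.08
L3->L4,SIS,3,0.26,0.08
L3->L4,SIS,4,-0.11,0.08
L3->L4,SIS,5,-0.10,0.08
L4->L2,SIS,1,8.69,0.17
L4->L2,SIS,2,8.49,0.17
L4->L2,SIS,3,8.59,0.17
L4->L2,SIS,4,7.11,0.17
L4->L2,SIS,5,7.62,0.17
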