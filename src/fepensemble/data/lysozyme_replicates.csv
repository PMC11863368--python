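transformation,condition,replicate,ddg_kjmol,sigma_kjmol
Ben->Phe,VIS,1,8.07,0.06
Ben->Phe,VIS,2,7.97,0.07
Ben->Phe,VIS,3,8.42,0.06
Ben->Phe,VIS,4,8.02,0.07
Ben->Phe,VIS,5,8.07,0.07
Eth->Tol,VIS,1,2.36,0.08
Eth->Tol,VIS,2,2.50,0.08
Eth->Tol,VIS,3,2.38,0.08
Eth->Tol,VIS,4,2.41,0.08
Eth->Tol,VIS,5,2.91,0.08
Tol->Ben,VIS,1,-0.19,0.07
Tol->Ben,VIS,2,-0.20,0.07
Tol->Ben,VIS,3,-0.08,0.07
Tol->Ben,VIS,4,-0.16,0.07
Tol->Ben,VIS,5,-0.33,0.07
Ide->Ido,VIS,1,7.63,0.06
Ide->Ido,VIS,2,7.62,0.06
Ide->Ido,VIS,3,6.61,0.06
Ide->Ido,VIS,4,8.01,0.06
Ide->Ido,VIS,5,7.75,0.06
Ido->Bzf,VIS,1,-11.92,0.05
Ido->Bzf,VIS,2,-11.73,0.05
Ido->Bzf,VIS,3,-11.51,0.05
Ido->Bzf,VIS,4,-9.81,0.05
Ido->Bzf,VIS,5,-11.48,0.05
Ide->Bzf,VIS,1,-3.78,0.06
Ide->Bzf,VIS,2,-3.86,0.06
Ide->Bzf,VIS,3,-3.99,0.06
Ide->Bzf,VIS,4,-4.20,0.06
Ide->Bzf,VIS,5,-3.87,0.06
Ben->Phe,SIS,1,8.02,0.07
Ben->Phe,SIS,2,8.09,0.07
Ben->Phe,SIS,3,8.04,0.07
Ben->Phe,SIS,4,8.15,0.07
Ben->Phe,SIS,5,8.42,0.07
Eth->Tol,SIS,1,3.29,0.08
Eth->Tol,SIS,2,2.84,0.08
Eth->Tol,SIS,3,2.91,0.08
Eth->Tol,SIS,4,3.26,0.08
Eth->Tol,SIS,5,3.33,0.08
Tol->Ben,SIS,1,-0.38,0.07
Tol->Ben,SIS,2,-0.51,0.07
Tol->Ben,SIS,3,-0.07,0.07
Tol->Ben,SIS,4,-0.72,0.07
Tol->Ben,SIS,5,0.39,0.07
Ide->Ido,SIS,1,7.29,0.06
Ide->Ido,SIS,2,7.00,0.07
Ide->Ido,SIS,3,7.67,0.06
Ide->Ido,SIS,4,7.01,0.06
Ide->Ido,SIS,5,7.35,0.06
Ido->Bzf,SIS,1,-12.09,0.05
Ido->Bzf,SIS,2,-11.92,0.05
Ido->Bzf,SIS,3,-11.59,0.05
Ido->Bzf,SIS,4,-11.52,0.05
Ido->Bzf,SIS,5,-12.90,0.05
Ide->Bzf,SIS,1,-4.42,0.06
Ide->Bzf,SIS,2,-4.37,0.07
Ide->Bzf,SIS,3,-3.62,0.07
Ide->Bzf,SIS,4,-4.12,0.06
Ide->Bzf,SIS,5,-4.26,0.06
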