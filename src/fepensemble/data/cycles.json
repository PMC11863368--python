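{
  "brd4": [["L3->L2", 1], ["L4->L2", -1], ["L3->L4", -1]],
  "lysozyme": [["Ide->Ido", 1], ["Ido->Bzf", 1], ["Ide->Bzf", -1]]
}
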