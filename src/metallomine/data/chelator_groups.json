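{
  "catechol": "EntA and EntC",
  "salicylate": "IPL or SalSyn",
  "hydroxamate": "(Orn_monoox and not (KtzT or MetRS-like)) or Lys_monoox or VbsL",
  "beta-OHAsp": "TBH_Asp or (IBH_Asp and not SBH_Asp) or CyanoBH_Asp1 or CyanoBH_Asp2",
  "beta-OHHis": "IBH_His",
  "graminine": "GrbD and GrbE",
  "Dmaq": "FbnL and FbnM",
  "pyoverdine-chromophore": "PvdO or PvdP",
  "NRPS-domain-marker": "VibH_like or Cy_tandem"
}
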