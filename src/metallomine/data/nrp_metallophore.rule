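# Canonical NRP-metallophore detection rule.
# Standalone NRPS-domain markers (VibH_like, Cy_tandem) trigger on their own;
# every chelator branch additionally requires a single gene carrying both a
# condensation and an adenylation (AMP-binding) domain.
VibH_like or Cy_tandem or
(cds(Condensation and AMP-binding) and (
   (IBH_Asp and not SBH_Asp) or IBH_His or TBH_Asp or
   CyanoBH_Asp1 or CyanoBH_Asp2 or
   IPL or SalSyn or (EntA and EntC) or
   (GrbD and GrbE) or (FbnL and FbnM) or PvdO or PvdP or
   (Orn_monoox and not (KtzT or MetRS-like)) or
   Lys_monoox or VbsL))
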