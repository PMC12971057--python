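# Toy profile registry: name, bitscore cutoff (bits), category, role.
# Cutoffs are illustrative defaults for synthetic data, not the calibrated
# values shipped with any published profile set.
EntA	200	catechol	marker
EntC	300	catechol	marker
IPL	100	salicylate	marker
SalSyn	350	salicylate	marker
VibH_like	250	NRPS-core	marker
Cy_tandem	400	NRPS-core	marker
Orn_monoox	300	hydroxamate	marker
Lys_monoox	300	hydroxamate	marker
VbsL	250	hydroxamate	marker
KtzT	150	negative-constraint	negative
MetRS-like	200	negative-constraint	negative
TBH_Asp	300	beta-OHAsp	marker
IBH_Asp	300	beta-OHAsp	marker
SBH_Asp	300	negative-constraint	negative
IBH_His	300	beta-OHHis	marker
CyanoBH_Asp1	300	beta-OHAsp	marker
CyanoBH_Asp2	300	beta-OHAsp	marker
GrbD	200	graminine	marker
GrbE	200	graminine	marker
FbnL	150	Dmaq	marker
FbnM	150	Dmaq	marker
PvdO	200	pyoverdine-chromophore	marker
PvdP	400	pyoverdine-chromophore	marker
Condensation	20	NRPS-core	core
AMP-binding	20	NRPS-core	core
PF00593	25	transporter	transporter
PF01032	22	transporter	transporter
PF01497	23	transporter	transporter
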