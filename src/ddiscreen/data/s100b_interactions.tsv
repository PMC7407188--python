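# Curated iPfam-style domain-domain interaction table for the two S100B domains.
# Columns: domain_acc	partner_acc	description
# Query domains: PF01023 (S_100) and PF00036 (EF-hand_1).
PF01023	PF00168	C2: structural domain involved in targeting proteins to membrane
PF01023	PF00036	EF-hand_1: helix-loop-helix Ca-binding motif
PF01023	PF01267	F-actin_cap_A: Ca-independent binder of fast-growing actin filament ends
PF01023	PF00167	FGF: fibroblast growth factor
PF01023	PF13895	Ig_2: immunoglobulin domain
PF01023	PF00340	IL1: interleukin-1
PF01023	PF01576	Myosin_tail_1: myosin tail
PF01023	PF01023	S_100: S100-type calcium-binding domain (homo-multimer)
PF01023	PF05002	SGS: domain found in calcyclin-binding proteins
PF00036	PF12424	ATP_Ca_trans_C: plasma-membrane calcium transporter ATPase C-terminal
PF00036	PF08763	CA_chan_IQ: voltage-gated calcium channel IQ domain
PF00036	PF12515	CaATP_NAI: Ca2+-ATPase N-terminal autoinhibitory domain
PF00036	PF02888	CaMBD: calmodulin-binding domain
PF00036	PF00307	CH: calponin homology domain
PF00036	PF00531	Death: death domain
PF00036	PF00036	EF-hand_1: helix-loop-helix Ca-binding motif
PF00036	PF13499	EF-hand_7: EF-hand domain pair
PF00036	PF13202	EF-hand_5: EF hand
PF00036	PF13405	EF-hand_6: EF-hand domain
PF00036	PF13833	EF-hand_8: EF-hand domain pair
PF00036	PF10163	EnY2: transcription factor e(y)2
PF00036	PF01267	F-actin_cap_A: F-actin capping protein alpha subunit
PF00036	PF00167	FGF: fibroblast growth factor
PF00036	PF00612	IQ: IQ calmodulin-binding motif
PF00036	PF03520	KCNQ_channel: KCNQ voltage-gated potassium channel
PF00036	PF01372	Melittin: melittin
PF00036	PF00149	Metallophos: calcineurin-like phosphoesterase
PF00036	PF00063	Myosin_head: myosin head (motor domain)
PF00036	PF00613	PI3KA: phosphoinositide 3-kinase accessory domain
PF00036	PF11522	Pik1: yeast phosphatidylinositol-4-OH kinase Pik1
PF00036	PF00069	Pkinase: protein kinase domain
PF00036	PF01023	S_100: S100-type calcium-binding domain
PF00036	PF12209	SAC3: leucine permease transcriptional regulator helical domain
PF00036	PF08457	Sfi1: Sfi1 spindle body protein
PF00036	PF01387	Synuclein: synuclein
PF00036	PF00992	Troponin: troponin
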