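# Screen series: one row per mutagen x background combination,
# with the number of mutagenized haploid genomes screened.
series_id	mutagen	background	haploid_genomes
EMS/WT	EMS	WT	1.18e5
ENU/WT	ENU	WT	1.27e5
EMS/Is[mddm]	EMS	TRANSGENE_RESCUE	0.95e5
ENU/Is[mddm]	ENU	TRANSGENE_RESCUE	0.32e5
EMS/acs-22	EMS	ACS22_NULL	1.49e5
ENU/acs-22	ENU	ACS22_NULL	1.49e5
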