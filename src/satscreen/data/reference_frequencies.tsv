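# Published per-gene allele frequencies (display units of 1e-5 per haploid
# genome) for the screen this package models, used by `satscreen reproduce`
# to report computed-vs-published agreement. deviation=true marks cells
# where the published table is internally inconsistent with its own
# footnote arithmetic (documented deviations, not failures).
gene_id	axis	key	published_1e5	deviation
maoc-1	mutagen	EMS	2.5	false
maoc-1	mutagen	ENU	1.6	false
maoc-1	background	WT	2.0	false
dhs-28	mutagen	EMS	7.6	false
dhs-28	mutagen	ENU	4.7	false
dhs-28	background	WT	6.1	false
daf-22	mutagen	EMS	15.3	false
daf-22	mutagen	ENU	3.9	false
daf-22	background	WT	9.4	false
prx-10	mutagen	EMS	0.9	false
prx-10	background	TRANSGENE_RESCUE	1.6	false
drop-1	mutagen	EMS	6.4	false
drop-1	mutagen	ENU	4.9	false
drop-1	background	WT	3.7	false
drop-1	background	TRANSGENE_RESCUE	3.1	false
drop-1	background	ACS22_NULL	8.4	false
drop-2	mutagen	EMS	8.0	false
drop-2	mutagen	ENU	3.1	false
drop-2	background	WT	4.1	false
drop-2	background	TRANSGENE_RESCUE	9.4	false
drop-3	mutagen	EMS	1.4	false
drop-3	mutagen	ENU	1.3	false
drop-3	background	WT	1.2	false
drop-3	background	TRANSGENE_RESCUE	1.6	false
drop-4	mutagen	ENU	0.3	false
drop-4	background	ACS22_NULL	0.3	false
drop-5	mutagen	EMS	0.9	false
drop-5	background	WT	0.4	false
drop-5	background	TRANSGENE_RESCUE	0.8	false
drop-6	mutagen	ENU	1.3	false
drop-6	background	WT	0.8	false
drop-7	mutagen	ENU	0.6	false
drop-7	background	WT	0.4	false
drop-8	mutagen	ENU	0.8	true
drop-8	background	ACS22_NULL	0.3	false
drop-9	mutagen	EMS	0.5	false
drop-9	background	WT	0.4	false
TOTAL	mutagen	EMS	43.5	false
TOTAL	mutagen	ENU	22.5	true
TOTAL	background	WT	28.5	false
TOTAL	background	TRANSGENE_RESCUE	16.5	false
TOTAL	background	ACS22_NULL	9.0	false
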