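# SYNTHETIC reconstruction of the 45 sequenced mutation sites of the four
# known genes: the per-class counts are the unique integer solutions to the
# published class percentages at n=32 (EMS) and n=13 (ENU); allele ids,
# gene assignments within each mutagen, and reported strands are arbitrary.
# Strands alternate so that strand canonicalization is exercised.
allele_id	gene_id	mutagen	kind	ref_base	alt_base	strand
ems01	maoc-1	EMS	substitution	G	A	plus
ems02	maoc-1	EMS	substitution	C	T	minus
ems03	maoc-1	EMS	substitution	G	A	plus
ems04	dhs-28	EMS	substitution	C	T	minus
ems05	dhs-28	EMS	substitution	G	A	plus
ems06	dhs-28	EMS	substitution	C	T	minus
ems07	dhs-28	EMS	substitution	G	A	plus
ems08	dhs-28	EMS	substitution	C	T	minus
ems09	dhs-28	EMS	substitution	G	A	plus
ems10	dhs-28	EMS	substitution	C	T	minus
ems11	dhs-28	EMS	substitution	G	A	plus
ems12	dhs-28	EMS	substitution	C	A	minus
ems13	daf-22	EMS	substitution	G	A	plus
ems14	daf-22	EMS	substitution	C	T	minus
ems15	daf-22	EMS	substitution	G	A	plus
ems16	daf-22	EMS	substitution	C	T	minus
ems17	daf-22	EMS	substitution	G	A	plus
ems18	daf-22	EMS	substitution	C	T	minus
ems19	daf-22	EMS	substitution	G	A	plus
ems20	daf-22	EMS	substitution	C	T	minus
ems21	daf-22	EMS	substitution	G	A	plus
ems22	daf-22	EMS	substitution	C	T	minus
ems23	daf-22	EMS	substitution	G	A	plus
ems24	daf-22	EMS	substitution	C	T	minus
ems25	daf-22	EMS	substitution	G	A	plus
ems26	daf-22	EMS	substitution	C	T	minus
ems27	daf-22	EMS	substitution	G	A	plus
ems28	daf-22	EMS	substitution	C	T	minus
ems29	daf-22	EMS	substitution	G	A	plus
ems30	daf-22	EMS	substitution	T	G	minus
ems31	prx-10	EMS	substitution	G	A	plus
ems32	prx-10	EMS	substitution	C	T	minus
enu01	maoc-1	ENU	substitution	G	A	plus
enu02	maoc-1	ENU	substitution	T	A	minus
enu03	dhs-28	ENU	substitution	G	A	plus
enu04	dhs-28	ENU	substitution	C	T	minus
enu05	dhs-28	ENU	substitution	G	A	plus
enu06	dhs-28	ENU	substitution	C	T	minus
enu07	dhs-28	ENU	substitution	G	T	plus
enu08	dhs-28	ENU	substitution	T	C	minus
enu09	daf-22	ENU	substitution	G	A	plus
enu10	daf-22	ENU	substitution	C	T	minus
enu11	daf-22	ENU	substitution	G	A	plus
enu12	daf-22	ENU	substitution	A	T	plus
enu13	daf-22	ENU	indel			plus
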