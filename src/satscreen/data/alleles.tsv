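# Isolated allele counts per complementation group per screen series
# (long format; omitted gene x series pairs are zero).
gene_id	series_id	count
maoc-1	EMS/WT	3
maoc-1	ENU/WT	2
dhs-28	EMS/WT	9
dhs-28	ENU/WT	6
daf-22	EMS/WT	18
daf-22	ENU/WT	5
prx-10	EMS/Is[mddm]	2
drop-1	EMS/WT	5
drop-1	ENU/WT	4
drop-1	EMS/Is[mddm]	2
drop-1	ENU/Is[mddm]	2
drop-1	EMS/acs-22	16
drop-1	ENU/acs-22	9
drop-2	EMS/WT	5
drop-2	ENU/WT	5
drop-2	EMS/Is[mddm]	12
drop-3	EMS/WT	3
drop-3	ENU/Is[mddm]	2
drop-4	ENU/acs-22	1
drop-5	EMS/WT	1
drop-5	EMS/Is[mddm]	1
drop-6	ENU/WT	2
drop-7	ENU/WT	1
drop-8	ENU/acs-22	1
drop-9	EMS/WT	1
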