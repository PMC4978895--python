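# Complementation groups with the background-eligibility attributes that
# determine in which screen series each gene's mutants can be isolated:
# bypassed_by_transgene excludes the rescue-transgene series,
# suppressed_by_acs22 excludes the acs-22 null series.
gene_id	linkage	bypassed_by_transgene	suppressed_by_acs22	temperature_sensitive	n_loci
maoc-1	II	true	true	false	1
dhs-28	X	true	true	false	1
daf-22	II	true	true	false	1
prx-10	III	false	true	false	1
drop-1	II	false	false	true	1
drop-2	IV	false	true	false	1
drop-3	IV	false	true	true	1
drop-4	X	false	false	false	1
drop-5	X	false	true	true	1
drop-6	X	false	true	true	1
drop-7	unknown	false	true	false	2
drop-8	III	false	false	true	1
drop-9	II	false	true	false	1
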