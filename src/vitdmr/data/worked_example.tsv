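study_id	exposure	outcome	beta	se	n	scale
pooled	score_synthesis	ln25ohd	2.83	0.1785714	146581	percent_per_allele
pooled	score_synthesis	sbp	-0.10	0.0535459	146581	per_allele
pooled	score_synthesis	dbp	-0.08	0.0331633	146581	per_allele
pooled	score_synthesis	hypertension	-0.0202027	0.0078499	142255	per_allele_log_odds
pooled	ln25ohd	sbp	-0.12	0.0408163	49363	per_10pct
pooled	ln25ohd	dbp	-0.02	0.0280612	49363	per_10pct
pooled	ln25ohd	hypertension	-0.0202027	0.0052063	49363	per_10pct_log_odds
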