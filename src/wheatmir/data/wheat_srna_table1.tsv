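library	distinct_reads	total_reads	singleton_distinct_pct	frac_20_24_pct
DG	2962991	10368525	80.76	80.80
GSE	3368098	10831734	82.58	79.99
SH	3802991	6295504	72.28	92.29
SL	1555132	4154639	77.07	82.17
SR	3060835	11368631	82.97	72.11
SJ	7754037	13025784	84.63	96.44
YS5	6428180	14036832	83.12	84.49
YS15	4841857	14355546	82.13	88.65
FL	2370690	7580952	87.22	89.60
GRA8	2796755	11843843	84.40	74.79
GRA15	7502165	14439188	83.16	89.23
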