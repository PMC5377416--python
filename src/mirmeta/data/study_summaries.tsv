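study_id	n_case	mean_case	sd_case	n_control	mean_control	sd_control	source
GSE69580	5	9.8928	13.2138	5	3.4452	1.3785	GEO
GSE54751	10	0.1380	0.1312	10	0.1882	0.1004	GEO
GSE41874	3	0.8520	0.1265	3	1.7150	0.2703	GEO
GSE40744	39	9.9121	1.3010	18	9.8072	0.4518	GEO
GSE21362	73	6.4679	1.5814	73	7.5048	0.9066	GEO
GSE22058	96	0.9892	0.3288	96	1.26766	0.1114	GEO
GSE12717	10	10.7535	1.3380	6	10.7052	0.3907	GEO
GSE57555	5	-0.0419	0.0056	16	-0.0211	0.0253	GEO
GSE10694	78	11.0580	0.5132	88	11.1343	0.4773	GEO
qPCR-combined-2016	89	0.7302	0.5142	89	1.3015	0.6934	qPCR
TCGA-2016	354	8.0304	1.6810	50	8.9665	0.8451	TCGA
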