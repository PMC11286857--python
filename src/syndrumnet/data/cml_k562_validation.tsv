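# Top-20 predicted drug combinations for chronic myeloid leukemia with K562
# in-vitro validation (WST-8 assay, 72 h). z_qa/z_qb are proximity z-scores
# between the CML module and each drug module; s_ab is the drug-drug
# separation; c_qa/c_qb are transcriptional correlations; score is the
# T+P+C prediction total. Survival columns are mean percentages; ca_score
# is the Loewe toxic unit and ia_score the tabulated independent-action
# score. Empty in-vitro fields mark pairs excluded from the wet-lab panel.
rank	drug_a	drug_b	z_qa	z_qb	s_ab	c_qa	c_qb	score	survival_a	survival_b	survival_combo	ca_score	ia_score
1	capsaicin	mitoxantrone	-7.72	-5.56	0.03	-0.18	-0.47	3.18	50.9	51.9	12.6	0.46	13.8
2	idarubicin	mitoxantrone	-5.13	-5.56	0.02	-0.46	-0.47	3.15	81.1	54.8	39.5	1	4.9
3	capsaicin	idarubicin	-7.72	-5.13	0.03	-0.18	-0.46	3.15	50.0	65.1	21.5	0.83	11.1
4	daunorubicin	mitoxantrone	-4.79	-5.56	0.01	-0.48	-0.47	3.13	69.6	54.5	35.9	0.55	2.0
5	mitoxantrone	topotecan	-5.56	-6.23	0.02	-0.47	-0.29	3.13	61.1	59.4	40.5	0.81	-4.2
6	capsaicin	daunorubicin	-7.72	-4.79	0.03	-0.18	-0.48	3.13	51.2	85.0	20.7	0.73	22.8
7	capsaicin	topotecan	-7.72	-6.23	0.03	-0.18	-0.29	3.13	55.8	61.0	28.1	0.48	5.9
8	fasudil	mitoxantrone	-4.16	-5.56	0.04	-0.50	-0.47	3.10	39.5	60.0	22.7	0.69	1.0
9	capsaicin	fasudil	-7.72	-4.16	0.04	-0.18	-0.50	3.10	53.8	39.5	15.0	1.02	6.3
10	daunorubicin	idarubicin	-4.79	-5.13	0.01	-0.48	-0.46	3.10	81.7	67.8	20.5	0.37	34.9
11	idarubicin	topotecan	-5.13	-6.23	0.02	-0.46	-0.29	3.10	65.9	59.4	42.7	0.77	-3.6
12	mitoxantrone	zofenopril	-5.56	-6.70	0.02	-0.47	0.16	3.10	64.6	109.2	54.3	1.72	16.1
13	acemetacin	mitoxantrone	-5.12	-5.56	0.04	-0.37	-0.47	3.10	92.3	64.6	47.7	1.15	11.9
14	capsaicin	zofenopril	-7.72	-6.70	0.02	-0.18	0.16	3.10	54.0	84.1	29.2	0.91	16.2
15	capsaicin	acemetacin	-7.72	-5.12	0.03	-0.18	-0.37	3.10	54.0	52.4	19.3	0.67	9.0
16	fludarabine	mitoxantrone	-6.97	-5.56	0.03	-0.12	-0.47	3.10	22.2	55.4	4.3	0.33	8.0
17	mitoxantrone	tiludronic acid	-5.56	-5.41	0.04	-0.47	0.32	3.10
18	capsaicin	fludarabine	-7.72	-6.97	0.03	-0.18	-0.12	3.10	58.6	66.0	17.0	0.8	21.7
19	capsaicin	tiludronic acid	-7.72	-5.41	0.04	-0.18	0.32	3.10
20	mitoxantrone	propranolol	-5.56	-4.37	0.03	-0.47	0.46	3.09
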