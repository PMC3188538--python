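# Published mutation rates (x 1e-7, mutants per cell division) of Pol delta
# proofreading-suppressor (eex) strains, with and without the pol3-01
# proofreading-deficient allele and with/without MSH6-dependent mismatch repair.
# Columns:
#   allele                  second-site eex substitution ("none" = base strain)
#   pol3_01_MSH6_foa        pol3-01,eex MSH6 rate, URA3/FOA reporter
#   pol3_01_MSH6_can        pol3-01,eex MSH6 rate, CAN1 reporter
#   pol3_01_msh6d_can       pol3-01,eex msh6-delta rate, CAN1 reporter
#   msh6d_effect            printed fold increase on MSH6 loss (pol3-01 background)
#   eex_MSH6_foa            pol3-eex MSH6 rate, URA3/FOA reporter
#   eex_msh6d_can           pol3-eex msh6-delta rate, CAN1 reporter
#   pol3_01_effect          printed fold increase on proofreading loss (msh6-delta background)
#   proofreading_ok         1 = eex msh6-delta rate within 2-fold of POL3 msh6-delta
#                           (asterisked entries; eex allele leaves proofreading intact)
# NA = not determined.  Rates are rounded as printed; fold columns are the
# published per-row ratios computed before rounding.
allele	pol3_01_MSH6_foa	pol3_01_MSH6_can	pol3_01_msh6d_can	msh6d_effect	eex_MSH6_foa	eex_msh6d_can	pol3_01_effect	proofreading_ok
none	23	135	NA	NA	0.3	23	NA	0
H879Y	5.7	53	11000	209	0.4	56	198	1
Y808C	5.5	31	7700	198	0.4	39	198	1
S968R	2.9	34	5200	153	0.3	23	226	1
A894V	2.4	33	3100	96	0.6	110	29	0
G204D	2.1	29	4500	157	0.7	54	84	1
E642K	1.6	23	2600	113	0.5	150	17	0
T711A	1.4	33	5900	179	0.3	22	275	1
W821C	1.3	33	2600	80	0.3	33	78	1
A786V	1.3	12	1600	135	0.1	80	19	0
F793I	1.2	6	1600	258	0.2	89	179	0
E594G	1.0	26	1700	63	0.2	15	107	1
R475I	0.9	14	2700	197	0.4	160	18	0
D831G	0.9	11	1700	150	0.9	64	27	0
E800K	0.7	13	1700	126	0.7	120	14	0
K891T	0.7	18	1900	103	0.3	220	9	0
H620Y	0.7	15	3700	248	0.3	26	141	1
V546M	0.5	14	2400	171	0.4	71	33	0
P614S	0.4	11	2100	185	0.5	130	16	0
Q563R	0.3	13	2000	158	0.3	120	17	0
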