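gene_id	eqtl_monocytes	eqtl_lcl_asthma	eqtl_lcl_ceu	gene_based	null_control	documented
HLA-DRB5	7.93e-7	1.60e-3	4.09e-6	7.57e-10	0.11	1
HLA-DRB1	7.93e-7	4.64e-6	4.09e-6	1.41e-11	0.59	1
GNGT2	1.11e-5	2.30e-4	1.83e-2	1.42e-2	0.48	1
HLA-DQA1	2.85e-5	7.73e-7	1.49e-3	2.90e-23	0.58	1
SLC22A5	1.85e-4	3.87e-5	2.66e-5	1.23e-6	0.46	1
STAT6	2.19e-4	2.75e-2	3.31e-2	1.94e-11	0.97	1
MPI	1.90e-3	2.02e-2	2.39e-2	1.12e-5	0.84	0
TLR6	3.63e-3	3.54e-3	6.69e-3	4.10e-2	0.93	1
DECR2	1.62e-2	4.32e-2	1.58e-4	2.22e-2	0.78	0
LNPEP	2.28e-2	5.55e-4	4.33e-2	3.98e-2	0.46	0
TTC19	2.52e-2	1.81e-2	2.20e-2	3.23e-2	0.30	0
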