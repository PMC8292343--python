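# Genes with candidate LoF germline variants in >=2 of the 19 WES patients,
# with carrier counts in non-LS (n=12), LS (n=7) and the ancestry-matched
# sporadic reference cohort (n=70). p_* columns are the printed two-sided
# Fisher p-values against the reference.
gene	n_nonls	n_ls	n_total	n_reference	p_nonls_printed	p_ls_printed
MLH1	0	7	7	2	>0.999	<0.0001
RECQL5	4	0	4	1	0.0013	>0.999
EME2	2	0	2	1	0.0547	>0.999
EP300	2	0	2	1	0.0547	>0.999
MUTYH	2	0	2	1	0.0547	>0.999
MSH3	2	0	2	2	0.1002	>0.999
COL7A1	2	0	2	4	0.2108	>0.999
PTCH1	2	0	2	7	0.6134	>0.999
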