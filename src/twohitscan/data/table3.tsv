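# Candidate LoF germline genes per WES patient and the genes with a somatic
# second hit (bi-allelic alteration) in at least one tumor.  A ":hc" suffix
# marks a high-confidence LoF germline variant; per-tumor multiplicities are
# not carried.  An empty biallelic_genes field means no second hit was seen
# in any sequenced tumor of that patient.
group	case_id	germline_lof_genes	n_tumors	n_sequenced	msi_status	biallelic_genes
LS	dou_002	MLH1,FANCL,RAD54L,RFC3,TSC2,FANCA,ARID1B,POLN	2	1	MSI-H/MSI-H	MLH1
LS	dou_003	MLH1:hc,POLL,SMO	3	3	MSI-H/MSI-H/MSI-H	MLH1,SMO
LS	dou_005	MLH1:hc,FANCI,UNG,POLN,RFC3,ARID1A	2	2	MSS/MSI-H	UNG,POLN,MLH1,ARID1A
LS	dou_006	MLH1,BRCA1:hc,CBL,RAD50,UVSSA	2	2	MSI-H/MSI-H	MLH1,RAD50
LS	dou_011	MLH1:hc,ARID2,ERCC2,EGFR,TMEM127,RHBDF2	2	2	MSI-H/MSI-H	ARID2,RHBDF2,MLH1
LS	dou_016	MLH1:hc,DCLRE1C,ERCC6,JAK3	3	3	MSI-H/MSI-H/MSI-H	MLH1
LS	dou_017	MLH1:hc,GNAS	2	2	MSI-H/MSI-H	MLH1
non_LS	dou_001	MUTYH,PBRM1,PTCH1,ABL1	2	2	MSS/MSS	MUTYH,PBRM1
non_LS	dou_004	CDH1,FANCI,FANCG:hc,FANCM,RAD50,MSH3	2	2	MSS/MSS	CDH1,FANCI,FANCG,FANCM
non_LS	dou_007	BRCA2,MUTYH,EME2,MBD4,RECQL5,WRN,COL7A1	2	1	MSS/NA	
non_LS	dou_008	AXIN1,COL7A1,RECQL5,MSH4,PTCH1,NEIL3,KLF4	2	2	MSS/MSS	COL7A1
non_LS	dou_009	NOTCH2,REV3L,RECQL5,SMARCA4,EP300,DOCK8	2	2	MSI-H/MSI-H	SMARCA4
non_LS	dou_010	CASP8:hc,EME2,NOTCH1	2	2	MSS/MSS	CASP8
non_LS	dou_012	POLM,EME1	2	2	MSS/MSS	EME1
non_LS	dou_013	FLCN,CIC,NFATC2IP,XAB2	2	2	MSS/MSS	FLCN
non_LS	dou_014	EP300,XPC,RECQL5	2	1	MSS/NA	
non_LS	dou_015	RAD52,CHEK2	2	2	MSS/MSS	RAD52
non_LS	dou_018	PARG,TET2,NF2,UVSSA,BCOR	2	2	MSS/MSS	PARG,TET2,UVSSA,NF2
non_LS	dou_019	MSH2,ERCC6,ALKBH2	2	2	MSS/MSS	ERCC6
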