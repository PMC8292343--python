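# Germline P/LP variants found by the 65-gene targeted panel: one row per
# variant (16 variants across 15 patients; dou_006 carries two).
# age_range: age at second diagnosis, printed only as a range for anonymity.
# msi_status: slash-joined per cancer type, order matching cancer_types.
case_id	cancer_types	age_range	gene	nucleotide_change	protein_change	mutation_type	consequence	acmg_criteria	printed_class	msi_status
dou_002	CRC/GC	<55	MLH1	c.1721T>C	p.Leu574Pro	Missense	missense	PM2,PP1,PP2,PP3,PP5	LP	MSI-H/MSI-H
dou_003	GC/CRC	<55	MLH1	c.1758dupC	p.Met587HisfsTer6	Frameshift_insertion	frameshift	PVS1,PM2	LP	MSI-H/MSI-H
dou_005	CRC/GC	<55	MLH1	c.208-1G>A	NA	Splice_acceptor_variant	splice_acceptor	PVS1,PM2,PP5	P	MSI-H/MSS
dou_006	GC/CRC	<55	MLH1	c.2041G>A	p.Ala681Thr	Missense	missense	PM2,PM5,PP3,PP5	LP	MSI-H/MSI-H
dou_006	GC/CRC	<55	BRCA1	c.213-1G>A	NA	Splice_acceptor_variant	splice_acceptor	PVS1,PM2,PP5	P	MSI-H/MSI-H
dou_011	GC/CRC	<55	MLH1	c.790+2T>A	NA	Splice_donor_variant	splice_donor	PVS1,PM2,PP5	P	MSI-H/MSI-H
dou_016	GC/CRC	<55	MLH1	c.1758dupC	p.Met587HisfsTer6	Frameshift_insertion	frameshift	PVS1,PM2	LP	MSI-H/MSI-H
dou_017	GC/CRC	<55	MLH1	c.1559-2A>C	NA	Splice	splice_acceptor	PVS1,PM2,PP5	P	MSI-H/MSI-H
dou_047	CRC/GC	>55	MSH6	c.829G>T	p.Glu277Ter	Splice_acceptor_variant	splice_acceptor	PVS1,PM2	LP	MSI-H/NA
dou_056	CRC/EC	>55	PMS2	c.1738A>T	p.Lys580Ter	Nonsense	stop_gained	PVS1,PM2,PP5	P	MSI-H/MSS
dou_061	CRC/EC	<55	MSH6	c.3477C>G	p.Tyr1159Ter	Nonsense	stop_gained	PVS1,PM2,PP5	P	NA/MSI-H
dou_062	CRC/EC	<55	PMS2	c.943C>T	p.Arg315Ter	Nonsense	stop_gained	PVS1,PM2,PP5	P	MSI-H/MSI-H
dou_065	CRC/EC	<55	MLH1	c.67G>T	p.Glu23Ter	Nonsense	stop_gained	PVS1,PM2,PP5	P	MSI-H/MSI-H
dou_069	CRC/EC/Klatskin	<55	MLH1	c.67G>T	p.Glu23Ter	Nonsense	stop_gained	PVS1,PM2,PP5	P	MSI-H/MSI-H/MSI-H
dou_070	EC/CRC/GC	<55	MLH1	exon_7-9_deletion	NA	Exon_deletion	exon_loss	PVS1,PM2	LP	MSI-H/NA/MSI-H
dou_071	CRC/GC/EC/Lung	<55	MSH2	c.942+3A>T	NA	Exon_loss	exon_loss	PVS1,PM2	LP	MSI-H/MSI-H/NA/MSI-H
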