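# Printed cohort margins used to reconstruct the clinical association tables.
# fh = family history (first-degree relatives with cancer); ge2 = two or more.
key	value
n_patients	71
n_ls_carriers	15
n_eo	30
n_ls_eo	13
n_fh_known	56
n_fh_ge2	24
n_ls_fh_known	10
n_ls_fh_ge2	9
n_ls_synchronous	6
n_nonls_wes	12
n_ls_wes	7
n_wes	19
n_reference	70
n_gc_crc	54
n_msih_patients	26
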