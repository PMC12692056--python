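dataset_id	n_tumor	n_control	control_kind	paired	selection
GSE15471	36	36	tumor_adjacent	true	microscopic
GSE16515	16	16	tumor_adjacent	true	microscopic
GSE32676	25	7	normal_pancreas	false	microscopic; >30% tumor cells
GSE71989	13	8	normal_pancreas	false	not specified
GSE17891	27	20	none	false	laser microdissection; 20 non-tumor samples are cell lines
GSE21654	0	22	none	false	cell-line panel (22 lines)
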