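clone_id	specificity	locus	v_gene	junction_aa	j_gene
Clone_81	islet	TRA	TRAV29/DV5	CAASRYSGGGADGLTF	TRAJ45
Clone_81	islet	TRB	TRBV12-4	CASSPQGGNTEAFF	TRBJ1-1
Clone_566	islet	TRA	TRAV29/DV5	CAASRYSGGGADGLTF	TRAJ45
Clone_566	islet	TRB	TRBV12-4	CASSVQGGNTEAFF	TRBJ1-1
P196-1	influenza	TRA	TRAV29/DV5	CAASRYSGGGADGLTF	TRAJ45
P196-1	influenza	TRB	TRBV12-4	CASSLQGGNTEAFF	TRBJ1-1
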