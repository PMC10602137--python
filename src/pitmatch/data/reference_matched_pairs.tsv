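pair_id	source	locus	v_gene	junction_aa	j_gene
1	IAR	TRA	TRAV1-2	CAVRMNTGFQKLVF	TRAJ8
1	PIT	TRA	TRAV1-2	CAVRMNTGFQKLVF	TRAJ8
1	IAR	TRB	TRBV11-2	CASSFGGGATDTQYF	TRBJ2-3
1	PIT	TRB	TRBV9	CASSVGMDPGLGYNEQFF	TRBJ2-1
2	IAR	TRA	TRAV12-1	CVVNDQAGTALIF	TRAJ15
2	PIT	TRA	TRAV12-1	CVVNDQAGTALIF	TRAJ15
2	IAR	TRB	TRBV7-2	CASSLDAGRNSPLHF	TRBJ1-6
2	PIT	TRB	TRBV20-1	CSARGYNSYEQYF	TRBJ2-7
3	IAR	TRA	TRAV12-1	CVVQGGSYIPTF	TRAJ6
3	PIT	TRA	TRAV12-1	CVVQGGSYIPTF	TRAJ6
3	IAR	TRB	TRBV5-4	CASSLVTSGENEQFF	TRBJ2-1
4	IAR	TRA	TRAV12-2	CAVNQAGTALIF	TRAJ15
4	PIT	TRA	TRAV12-2	CAVNQAGTALIF	TRAJ15
4	IAR	TRB	TRBV28	CASSFGSGADYGYTF	TRBJ1-2
4	PIT	TRB	TRBV29-1	CSVFDWDRGPGELFF	TRBJ2-2
5	IAR	TRA	TRAV12-2	CAVRSNFGNEKLTF	TRAJ48
5	PIT	TRA	TRAV12-2	CAVRSNFGNEKLTF	TRAJ48
5	IAR	TRB	TRBV19	CASGTDSYEQYF	TRBJ2-7
5	PIT	TRB	TRBV28	CASRTTGGTEAFF	TRBJ1-1
6	IAR	TRA	TRAV13-1	CAASIGTGTASKLTF	TRAJ44
6	PIT	TRA	TRAV13-1	CAASIGTGTASKLTF	TRAJ44
6	IAR	TRB	TRBV9	CASSVAGGGYEQYF	TRBJ2-7
6	PIT	TRB	TRBV24-1	CATSDPSGGGGNEQFF	TRBJ2-1
7	IAR	TRA	TRAV41	CAASNTGNQFYF	TRAJ49
7	PIT	TRA	TRAV41	CAASNTGNQFYF	TRAJ49
7	IAR	TRB	TRBV28	CAIGGRVYNEQFF	TRBJ2-1
7	PIT	TRB	TRBV5-1	CASSGSNYGYTF	TRBJ1-2
8	IAR	TRA	TRAV5	CAERGLTGGGNKLTF	TRAJ10
8	PIT	TRA	TRAV5	CAERGLTGGGNKLTF	TRAJ10
8	IAR	TRB	TRBV9	CASSVGGDFYNEQFF	TRBJ2-1
8	PIT	TRB	TRBV12-5	CASGLTRGSTDTQYF	TRBJ2-3
9	IAR	TRA	TRAV8-2	CVVSGGSNYKLTF	TRAJ53
9	PIT	TRA	TRAV8-2	CVVSGGSNYKLTF	TRAJ53
9	IAR	TRB	TRBV29-1	CSAHGGGGTEAFF	TRBJ1-1
9	PIT	TRB	TRBV6-1	CASSQGTPQYNEQFF	TRBJ2-1
10	IAR	TRA	TRAV8-3	CAVGPTGTASKLTF	TRAJ44
10	PIT	TRA	TRAV8-3	CAVGPTGTASKLTF	TRAJ44
10	IAR	TRB	TRBV7-6	CASSTNHQETQYF	TRBJ2-5
10	PIT	TRB	TRBV3-1	CASSGTGTGGLSPQETQYF	TRBJ2-5
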