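set_id	role	locus	v_gene	junction_aa	j_gene
GADp15	reference	TRA	TRAV41	CAAAGNQFYF	TRAJ49
GADp15	variant	TRA	TRAV29/DV5	CAARGNQFYF	TRAJ49
GADp15	variant	TRA	TRAV21	CAAIGNQFYF	TRAJ49
GADp15	variant	TRA	TRAV29/DV5	CAASAGNQFYF	TRAJ49
IGRP39	reference	TRA	TRAV25	CAGQTGANNLFF	TRAJ36
IGRP39	variant	TRA	TRAV16	CALQTGANNLFF	TRAJ36
IGRP39	variant	TRA	TRAV13-1	CATQTGANNLFF	TRAJ36
IGRP39	variant	TRA	TRAV24	CASQTGANNLFF	TRAJ36
ZNP1	reference	TRA	TRAV13-1	CAASGANSGYALNF	TRAJ41
ZNP1	variant	TRA	TRAV8-4	CAVSGANSGYALNF	TRAJ41
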