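gene	GATA-1|MZF1,Nkx-2.5,MYOD	MZF1|GATA-1,AP4/AML	Nkx-2.5|GATA-1,AP4/AML	AML-1a|GATA-2,AP2	MYOD|GATA-1,AP4/AML,CdxA	ZID|GATA-2,AP2	AP2|ZID,AML-1a	CdxA|MYOD,GATA-2	AP4/AML|MZF1,Nkx-2.5,MYOD	GATA-2|CdxA,ZID,AML-1a
C1qa		*	*
Chst7	*	*	*
C1qb	*	*	*	*		*	*
Emr1			*				*
Cd5l			*
Ambp	*	*	*
Bambi		*
Cxcl10					*		*
Igfbp1	*	*	*		*				*
Gad1							*
Clu		*			*
Slc43a3							*
Gas6		*
Lbp		*
Adamts1				*		*	*
Slc9a3r1	*	*	*	*	*	*	*	*	*	*
Mafb	*	*	*	*	*	*	*	*	*	*
Krt18	*	*	*	*		*	*		*
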