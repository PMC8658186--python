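# Curated list of differentially expressed B. rapa AGP genes in floral buds
# of the male-sterile (A) vs male-fertile (B) 'Bcajh97-01A/B' system across
# five microspore developmental stages (s1 pollen mother cell .. s5 mature
# pollen). Cells hold the fertile/sterile log2 fold change, "S"/"F" for
# sterile-/fertile-specific expression, or "." for no difference/expression.
subfamily	gene_name	locus	s1	s2	s3	s4	s5
AG-peptide	BrAGP12.2	Bra039397	.	.	.	-3.2	1.4
AG-peptide	BrAGP16.1	Bra004546	.	.	.	-2.2	.
AG-peptide	BrAGP16.2	Bra000419	1.2	.	1.9	1.1	2.8
AG-peptide	BrAGP22.1	Bra003071	.	.	.	-2.7	2.7
AG-peptide	BrAGP23.2	Bra014611	1.5	.	F	9.0	F
AG-peptide	BrAGP24	Bra025551	F	F	F	4.5	3.4
AG-peptide	BrAGP40.2	Bra023919	1.1	F	F	5.8	F
AG-peptide	BrAGP46	Bra008765	F	F	2.5	2.6	F
Classical	BrAGP1.1	Bra024284	.	-1.0	-1.1	.	-2.4
Classical	BrAGP1.2	Bra031924	.	.	.	-1.3	-2.3
Classical	BrAGP2.1	Bra038521	-1.3	.	.	1.2	-1.5
Classical	BrAGP6	Bra008762	.	F	F	2.6	6.7
Classical	BrAGP10.2	Bra000670	.	.	.	-1.8	-3.1
Classical	BrAGP11.2	Bra040548	1.1	S	.	7.5	9.4
Classical	BrAGP27	Bra040224	.	1.4	.	2.3	-2.0
Classical	BrAGP50.3	Bra012505	.	.	S	.	F
Classical	BrAGP54.1	Bra011948	.	.	1.6	F	F
Lys-rich	BrAGP17	Bra039184	1.7	.	2.6	5.6	.
Non-classical	BrAGP58.1	Bra040103	.	.	.	1.8	-1.8
Non-classical	BrAGP58.2	Bra021074	.	.	.	1.0	-2.0
FLA	BrFLA1	Bra000566	.	.	F	1.4	8.7
FLA	BrFLA2	Bra001464	F	F	F	6.5	12.1
FLA	BrFLA8	Bra005920	1.1	F	F	.	S
FLA	BrFLA13	Bra010241	F	F	6.1	F	F
FLA	BrFLA19	Bra025535	.	1.7	.	.	.
FLA	BrFLA24	Bra029925	.	.	1.1	.	-2.2
FLA	BrFLA25	Bra032093	.	S	F	F	F
FLA	BrFLA28	Bra034746	.	.	8.2	8.4	11.4
FLA	BrFLA32	Bra038741	.	.	8.2	8.4	11.4
FLA	BrFLA36	Bra023589	-2.9	2.2	.	-3.6	1.5
PLA	BrENODL3	Bra001712	F	1.1	8.9	F	F
PLA	BrENODL7	Bra003532	S	.	3.3	6.0	.
PLA	BrENODL28	Bra022335	F	F	F	F	F
PLA	BrENODL32	Bra023981	.	.	.	.	-3.7
PLA	BrENODL42	Bra032131	S	5.6	-4.3	F	S
PLA	BrENODL43	Bra033326	.	1.0	-4.0	F	F
PLA	BrENODL49	Bra037575	F	F	F	F	F
PLA	BrSCL1	Bra002283	-1.4	-1.7	.	-1.7	6.3
PLA	BrSCL5	Bra020092	F	F	F	3.4	F
PLA	BrUCL1	Bra000364	-2.4	.	-2.2	-4.7	-3.9
PLA	BrUCL7	Bra009259	2.3	-1.9	F	S	S
PLA	Bra019044	Bra019044	.	.	.	-2.3	.
XYLP	BrXYLP3	Bra013135	.	-1.4	.	2.0	-2.1
XYLP	BrXYLP5	Bra000652	F	2.3	F	7.1	8.9
XYLP	BrXYLP9	Bra036905	1.1	F	1.9	.	-5.7
XYLP	BrXYLP13	Bra001874	F	F	S	S	S
XYLP	BrXYLP15	Bra025919	F	2.5	7.7	7.4	F
XYLP	BrXYLP16	Bra016563	.	2.7	.	10.4	10.5
XYLP	BrXYLP17	Bra031024	F	F	F	F	10.4
XYLP	BrXYLP21	Bra032857	.	.	.	-3.3	1.9
XYLP	BrXYLP23	Bra021455	.	4.8	-7.0	-1.7	-3.0
XYLP	BrXYLP25	Bra001875	F	1.7	.	-6.0	-5.2
XYLP	BrXYLP27	Bra032462	F	F	3.0	-3.9	-2.2
XYLP	BrXYLP29	Bra025907	.	-1.8	F	1.6	2.0
CAGP	BrCAGP2	Bra039574	F	F	F	F	F
CAGP	BrCAGP7	Bra014398	F	2.7	-2.0	1.0	S
CAGP	BrCAGP9	Bra001983	.	1.1	-2.4	1.0	-1.2
CAGP	BrCAGP13	Bra010330	.	.	.	1.4	1.7
CAGP	BrCAGP24	Bra040283	F	1.1	-2.4	F	8.7
CAGP	BrCAGP28	Bra036815	F	F	F	F	F
CAGP	BrCAGP33	Bra039561	.	.	1.5	1.4	3.7
CAGP	BrCAGP37	Bra037087	S	F	F	.	7.2
CAGP	BrCAGP55	Bra011048	2.1	3.7	S	-2.5	2.3
CAGP	BrCAGP67	Bra022410	.	2.1	.	.	.
CAGP	BrCAGP71	Bra035635	1.6	.	1.2	-2.6	2.9
CAGP	BrCAGP73	Bra021861	.	.	.	-1.9	-1.7
CAGP	BrCAGP81	Bra026880	.	F	.	-1.8	-2.6
CAGP	BrCAGP88	Bra036147	F	F	F	5.1	4.1
CAGP	BrCAGP92	Bra001249	.	.	1.3	1.6	.
CAGP	BrCAGP94	Bra006651	2.0	.	-3.4	.	-1.7
CHAE	BrCHAE1	Bra013339	.	1.3	1.4	.	.
HAE	BrHAE1	Bra030020	S	F	2.2	1.0	F
HAE	BrHAE3	Bra014023	-1.5	3.1	1.7	5.1	.
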