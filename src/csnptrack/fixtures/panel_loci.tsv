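rsid	chrom	pos	gene	alleles	annotation
rs1051614	1	154744807	KCNN3	C/G	synonymous
rs12990557	2	202342402	STRADB	G/T	synonymous
rs2279819	3	125726048	SLC41A3	G/C	synonymous
rs231399	4	2831383	SH3BP2	T/G	synonymous
rs2304035	5	168176517	SLIT3	A/G	synonymous
rs3734557	6	40360465	LRFN2	A/G	synonymous
rs12179	7	150557622	AOC1	G/A	synonymous
rs6559167	8	6389889	ANGPT2	C/A/G	synonymous
rs2297079	9	421032	DOCK8	C/G	synonymous
rs12221474	10	99332488	ANKRD2	A/C	synonymous
rs3741097	11	134244123	GLB1L2	C/G	synonymous
rs4758686	12	122623000	MLXIP	T/C	synonymous
rs5960	13	113801737	F10	C/T	synonymous
rs3737171	14	57052511	TMEM260	G/T	synonymous
rs3743399	15	89398330	ACAN	G/A	synonymous
rs8048410	16	1614097	IFT140	A/G	synonymous
rs6503070	17	7948175	ALOX15B	C/T	synonymous
rs3744877	18	77894844	ADNP2	G/A	synonymous
rs1128925	19	2767192	SGTA	G/T	synonymous
rs6061243	20	61040453	GATA5	C/G	synonymous
rs2249057	21	47773103	PCNT	C/A	synonymous
rs9620123	22	43614316	SCUBE1	C/G	synonymous
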