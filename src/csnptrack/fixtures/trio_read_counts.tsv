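sample	rsid	allele	count
C	rs1051614	C	13
C	rs1051614	G	4
M	rs1051614	C	21
F	rs1051614	G	14
C	rs12990557	C	51
C	rs12990557	A	14
M	rs12990557	C	67
M	rs12990557	A	13
F	rs12990557	C	71
F	rs12990557	A	28
C	rs2279819	C	21
C	rs2279819	G	14
M	rs2279819	C	16
M	rs2279819	G	10
F	rs2279819	C	14
F	rs2279819	G	15
C	rs231399	A	41
M	rs231399	A	37
F	rs231399	A	33
C	rs2304035	C	16
C	rs2304035	T	7
M	rs2304035	C	12
M	rs2304035	T	12
F	rs2304035	T	25
C	rs3734557	A	30
M	rs3734557	A	13
M	rs3734557	G	9
F	rs3734557	A	14
C	rs12179	A	27
C	rs12179	G	21
M	rs12179	A	14
M	rs12179	G	24
F	rs12179	A	42
C	rs6559167	T	51
M	rs6559167	T	45
F	rs6559167	T	17
F	rs6559167	C	17
C	rs2297079	G	26
C	rs2297079	C	20
M	rs2297079	G	19
M	rs2297079	C	14
F	rs2297079	G	8
F	rs2297079	C	28
C	rs12221474	T	18
C	rs12221474	G	17
M	rs12221474	G	25
F	rs12221474	T	35
C	rs3741097	G	12
C	rs3741097	C	9
M	rs3741097	G	33
F	rs3741097	G	13
F	rs3741097	C	8
C	rs4758686	C	8
C	rs4758686	T	18
M	rs4758686	T	28
F	rs4758686	C	24
C	rs5960	T	13
C	rs5960	C	25
M	rs5960	C	35
F	rs5960	T	41
C	rs3737171	A	29
M	rs3737171	A	29
F	rs3737171	A	40
C	rs3743399	T	28
M	rs3743399	T	8
M	rs3743399	C	21
F	rs3743399	T	16
F	rs3743399	C	20
C	rs8048410	A	7
C	rs8048410	G	16
M	rs8048410	A	25
F	rs8048410	A	13
F	rs8048410	G	13
C	rs6503070	C	5
C	rs6503070	T	3
M	rs6503070	C	7
M	rs6503070	T	16
F	rs6503070	C	9
F	rs6503070	T	4
C	rs3744877	C	30
C	rs3744877	T	17
M	rs3744877	C	6
M	rs3744877	T	7
F	rs3744877	C	9
C	rs1128925	C	31
M	rs1128925	C	22
M	rs1128925	A	19
F	rs1128925	C	12
F	rs1128925	A	12
C	rs6061243	G	38
M	rs6061243	G	31
F	rs6061243	G	39
C	rs2249057	G	38
C	rs2249057	T	17
M	rs2249057	G	30
F	rs2249057	G	52
C	rs9620123	G	28
C	rs9620123	C	32
M	rs9620123	G	29
M	rs9620123	C	19
F	rs9620123	G	37
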