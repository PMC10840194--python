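rsid	DP	PE	MP	PIC	TPI	HWE_p
rs12221474	0.607	0.212	0.393	0.370	1.060	0.576
rs5960	0.608	0.212	0.392	0.370	1.060	0.578
rs6061243	0.625	0.173	0.375	0.370	0.970	0.850
rs1128925	0.615	0.203	0.385	0.370	1.040	0.851
rs9620123	0.609	0.212	0.391	0.370	1.060	0.707
rs8048410	0.649	0.122	0.351	0.370	0.850	0.117
rs6503070	0.601	0.188	0.399	0.360	1.000	0.694
rs231399	0.640	0.159	0.360	0.370	0.930	0.457
rs12990557	0.600	0.229	0.400	0.370	1.100	0.452
rs2297079	0.624	0.188	0.376	0.370	1.000	1.000
rs12179	0.640	0.152	0.360	0.370	0.920	0.446
rs3734557	0.631	0.162	0.369	0.370	0.940	0.700
rs1051614	0.638	0.139	0.362	0.370	0.890	0.130
rs2279819	0.647	0.145	0.353	0.370	0.900	0.266
rs2304035	0.601	0.220	0.399	0.370	1.080	0.454
rs6559167	0.765	0.169	0.235	0.510	0.960	0.001
rs3741097	0.637	0.165	0.363	0.370	0.950	0.576
rs4758686	0.643	0.139	0.357	0.370	0.890	0.256
rs3737171	0.625	0.188	0.375	0.370	1.000	1.000
rs3744877	0.638	0.162	0.362	0.370	0.940	0.572
rs2249057	0.549	0.212	0.451	0.340	1.060	0.053
rs3743399	0.602	0.195	0.398	0.370	1.020	0.696
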