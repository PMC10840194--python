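rsid	allele	frequency	theoretical_frequency
rs12221474	A	0.544	0.471
rs12221474	C	0.456	0.529
rs5960	C	0.535	0.476
rs5960	T	0.465	0.524
rs6061243	C	0.566	0.539
rs6061243	G	0.434	0.461
rs1128925	G	0.478	0.483
rs1128925	T	0.522	0.517
rs9620123	C	0.474	0.473
rs9620123	G	0.526	0.527
rs8048410	A	0.564	0.433
rs8048410	G	0.436	0.567
rs6503070	C	0.610	0.591
rs6503070	T	0.390	0.409
rs231399	T	0.513	0.529
rs231399	G	0.487	0.471
rs12990557	G	0.491	0.506
rs12990557	T	0.509	0.494
rs2297079	C	0.522	0.501
rs2297079	G	0.478	0.499
rs12179	G	0.456	0.520
rs12179	A	0.544	0.480
rs3734557	A	0.438	0.472
rs3734557	G	0.562	0.528
rs1051614	C	0.570	0.480
rs1051614	G	0.430	0.520
rs2279819	G	0.487	0.497
rs2279819	C	0.513	0.503
rs2304035	A	0.548	0.504
rs2304035	G	0.452	0.496
rs6559167	C	0.124	0.145
rs6559167	A	0.376	0.409
rs6559167	G	0.500	0.446
rs3741097	C	0.482	0.491
rs3741097	G	0.518	0.509
rs4758686	T	0.439	0.507
rs4758686	C	0.561	0.493
rs3737171	G	0.513	0.527
rs3737171	T	0.487	0.473
rs3744877	G	0.473	0.424
rs3744877	A	0.527	0.576
rs2249057	C	0.675	0.616
rs2249057	A	0.325	0.384
rs3743399	G	0.596	0.509
rs3743399	A	0.404	0.491
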