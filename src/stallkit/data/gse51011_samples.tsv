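sample_id	name	rep	data_type	target	org	model	input_baseline
GSM1234471	Eu-myc.Myc.C.1	1/1	ChIP-Seq	Myc	mmu	Eμ-myc	GSM1395178
GSM1395178	Eu-myc.input.C1	1/1	ChIP-Seq	Myc	mmu	Eμ-myc	–
GSM1234472	Eu-myc.Myc.P.1	1/3	ChIP-Seq	Myc	mmu	Eμ-myc	GSM1395179
GSM1395179	Eu-myc.input.P1	1/1	ChIP-Seq	Myc	mmu	Eμ-myc	–
GSM1234473	Eu-myc.Myc.P.2	2/3	ChIP-Seq	Myc	mmu	Eμ-myc	GSM1234498
GSM1234474	Eu-myc.Myc.P.3	3/3	ChIP-Seq	Myc	mmu	Eμ-myc	GSM1234498
GSM1234475	Eu-myc.Myc.T.1	1/1	ChIP-Seq	Myc	mmu	Eμ-myc	GSM1234498
GSM1234476	Eu-myc.Myc.T.2	1/1	ChIP-Seq	Myc	mmu	Eμ-myc	GSM1234498
GSM1234477	Eu-myc.Myc.T.3	1/1	ChIP-Seq	Myc	mmu	Eμ-myc	GSM1234498
GSM1234478	Eu-myc.Pol2.C.1	1/1	ChIP-Seq	Pol2	mmu	Eμ-myc	GSM1234498
GSM1234479	Eu-myc.Pol2.P.1	1/1	ChIP-Seq	Pol2	mmu	Eμ-myc	GSM1234498
GSM1234480	Eu-myc.Pol2.T.1	1/1	ChIP-Seq	Pol2	mmu	Eμ-myc	GSM1234498
GSM1234481	Eu-myc.Pol2.T.2	1/1	ChIP-Seq	Pol2	mmu	Eμ-myc	GSM1234498
GSM1234482	Eu-myc.Pol2.T.3	1/1	ChIP-Seq	Pol2	mmu	Eμ-myc	GSM1234498
GSM1234483	Eu-myc.H3K4me3.C1	1/2	ChIP-Seq	H3K4me3	mmu	Eμ-myc	GSM1234498
GSM1234517	Eu-myc.H3K4me3.C2	2/2	ChIP-Seq	H3K4me3	mmu	Eμ-myc	GSM1234498
GSM1234484	Eu-myc.H3K4me3.P1	1/2	ChIP-Seq	H3K4me3	mmu	Eμ-myc	GSM1234498
GSM1234518	Eu-myc.H3K4me3.P2	2/2	ChIP-Seq	H3K4me3	mmu	Eμ-myc	GSM1234498
GSM1234485	Eu-myc.H3K4me3.T1	1/1	ChIP-Seq	H3K4me3	mmu	Eμ-myc	GSM1234498
GSM1234486	Eu-myc.H3K4me3.T2	1/1	ChIP-Seq	H3K4me3	mmu	Eμ-myc	GSM1234498
GSM1234487	Eu-myc.H3K4me3.T3	1/1	ChIP-Seq	H3K4me3	mmu	Eμ-myc	GSM1234498
GSM1234488	Eu-myc.H3K4me1.C1	1/2	ChIP-Seq	H3K4me1	mmu	Eμ-myc	GSM1234498
GSM1234519	Eu-myc.H3K4me1.C2	2/2	ChIP-Seq	H3K4me1	mmu	Eμ-myc	GSM1234498
GSM1234489	Eu-myc.H3K4me1.P1	1/2	ChIP-Seq	H3K4me1	mmu	Eμ-myc	GSM1234498
GSM1234520	Eu-myc.H3K4me1.P2	2/2	ChIP-Seq	H3K4me1	mmu	Eμ-myc	GSM1234498
GSM1234490	Eu-myc.H3K4me1.T1	1/1	ChIP-Seq	H3K4me1	mmu	Eμ-myc	GSM1234498
GSM1234491	Eu-myc.H3K4me1.T2	1/1	ChIP-Seq	H3K4me1	mmu	Eμ-myc	GSM1234498
GSM1234492	Eu-myc.H3K4me1.T3	1/1	ChIP-Seq	H3K4me1	mmu	Eμ-myc	GSM1234498
GSM1234493	Eu-myc.H3K27ac.C	1/1	ChIP-Seq	H3K27ac	mmu	Eμ-myc	GSM1234498
GSM1234494	Eu-myc.H3K27ac.P	1/1	ChIP-Seq	H3K27ac	mmu	Eμ-myc	GSM1234498
GSM1234495	Eu-myc.H3K27ac.T1	1/1	ChIP-Seq	H3K27ac	mmu	Eμ-myc	GSM1234498
GSM1234496	Eu-myc.H3K27ac.T2	1/1	ChIP-Seq	H3K27ac	mmu	Eμ-myc	GSM1234498
GSM1234497	Eu-myc.H3K27ac.T3	1/1	ChIP-Seq	H3K27ac	mmu	Eμ-myc	GSM1234498
GSM1234498	Eu-myc.input.CPT	1/1	ChIP-Seq	–	mmu	Eμ-myc	–
GSM1386348	3T9.Serum.Myc.t0h	1/1	ChIP-Seq	Myc	mmu	3T9.Serum	GSM1386351
GSM1386349	3T9.Serum.Myc.t1h	1/1	ChIP-Seq	Myc	mmu	3T9.Serum	GSM1386351
GSM1386350	3T9.Serum.Myc.t2h	1/1	ChIP-Seq	Myc	mmu	3T9.Serum	GSM1386351
GSM1386351	3T9.Serum.input	1/1	ChIP-Seq	–	mmu	3T9.Serum	–
GSM1234500	P493.Myc.LowMyc	1/1	ChIP-Seq	Myc	hsa	P493	GSM1386347
GSM1234501	P493.Myc.HighMyc	1/1	ChIP-Seq	Myc	hsa	P493	GSM1386347
GSM1234499	P493.Myc.t0h	1/1	ChIP-Seq	Myc	hsa	P493	GSM1386347
GSM1386342	P493.Myc.t1h	1/1	ChIP-Seq	Myc	hsa	P493	GSM1386347
GSM1386343	P493.Myc.t24h	1/1	ChIP-Seq	Myc	hsa	P493	GSM1386347
GSM1234502	P493.Pol2.t0h	1/1	ChIP-Seq	Pol2	hsa	P493	GSM1386347
GSM1386344	P493.Pol2.t24h	1/1	ChIP-Seq	Pol2	hsa	P493	GSM1386347
GSM1386345	P493.H3K4me3.t24h	1/1	ChIP-Seq	H3K4me3	hsa	P493	GSM1386347
GSM1386346	P493.H3K27ac.t24h	1/1	ChIP-Seq	H3K27ac	hsa	P493	GSM1386347
GSM1386347	P493.input	1/1	ChIP-Seq	–	hsa	P493	–
GSM1234505	3T9.mycER.Pol2.0hOHT	1/1	ChIP-Seq	Pol2	mmu	3T9.mycER	GSM1234507
GSM1234506	3T9.mycER.Pol2.4hOHT	1/1	ChIP-Seq	Pol2	mmu	3T9.mycER	GSM1234507
GSM1234507	3T9.mycER.input.Pol2	1/1	ChIP-Seq	-	mmu	3T9.mycER	-
GSM1234508	3T9.mycER.Myc.0hOHT	1/1	ChIP-Seq	Myc	mmu	3T9.mycER	GSM1234516
GSM1234509	3T9.mycER.Myc.4hOHT	1/1	ChIP-Seq	Myc	mmu	3T9.mycER	GSM1234516
GSM1234510	3T9.mycER.H3K4me3.0hOHT	1/1	ChIP-Seq	H3K4me3	mmu	3T9.mycER	GSM1234516
GSM1234511	3T9.mycER.H3K4me3.4hOHT	1/1	ChIP-Seq	H3K4me3	mmu	3T9.mycER	GSM1234516
GSM1234512	3T9.mycER.H3K4me1.0hOHT	1/1	ChIP-Seq	H3K4me1	mmu	3T9.mycER	GSM1234516
GSM1234513	3T9.mycER.H3K4me1.4hOHT	1/1	ChIP-Seq	H3K4me1	mmu	3T9.mycER	GSM1234516
GSM1234514	3T9.mycER.H3K27ac.0hOHT	1/1	ChIP-Seq	H3K27ac	mmu	3T9.mycER	GSM1234516
GSM1234515	3T9.mycER.H3K27ac.4hOHT	1/1	ChIP-Seq	H3K27ac	mmu	3T9.mycER	GSM1234516
GSM1234516	3T9.mycER.input.OHT	1/1	ChIP-Seq	–	mmu	3T9.mycER	–
GSM1234734	Eu-myc.RNAseq.C_1	1/4	RNA-Seq	totRNA	mmu	Eμ-myc	–
GSM1234735	Eu-myc.RNAseq.C_3	2/4	RNA-Seq	totRNA	mmu	Eμ-myc	–
GSM1234736	Eu-myc.RNAseq.C_4	3/4	RNA-Seq	totRNA	mmu	Eμ-myc	–
GSM1234737	Eu-myc.RNAseq.C_6	4/4	RNA-Seq	totRNA	mmu	Eμ-myc	–
GSM1234738	Eu-myc.RNAseq.P_2	1/4	RNA-Seq	totRNA	mmu	Eμ-myc	GSM1234734-7
GSM1234739	Eu-myc.RNAseq.P_3	2/4	RNA-Seq	totRNA	mmu	Eμ-myc	GSM1234734-7
GSM1234740	Eu-myc.RNAseq.P_4	3/4	RNA-Seq	totRNA	mmu	Eμ-myc	GSM1234734-7
GSM1234741	Eu-myc.RNAseq.P_5	4/4	RNA-Seq	totRNA	mmu	Eμ-myc	GSM1234734-7
GSM1234742	Eu-myc.RNAseq.T_1	1/1	RNA-Seq	totRNA	mmu	Eμ-myc	GSM1234734-7
GSM1234743	Eu-myc.RNAseq.T_2	1/1	RNA-Seq	totRNA	mmu	Eμ-myc	GSM1234734-7
GSM1234744	Eu-myc.RNAseq.T_3	1/1	RNA-Seq	totRNA	mmu	Eμ-myc	GSM1234734-7
GSM1234745	3T9.mycER.RNAseq.0hOHT_1	1/4	RNA-Seq	totRNA	mmu	3T9.mycER	–
GSM1234746	3T9.mycER.RNAseq.0hOHT_2	2/4	RNA-Seq	totRNA	mmu	3T9.mycER	–
GSM1234747	3T9.mycER.RNAseq.0hOHT_3	3/4	RNA-Seq	totRNA	mmu	3T9.mycER	–
GSM1234748	3T9.mycER.RNAseq.0hOHT_4	4/4	RNA-Seq	totRNA	mmu	3T9.mycER	–
GSM1234749	3T9.mycER.RNAseq.4hOHT_1	1/4	RNA-Seq	totRNA	mmu	3T9.mycER	GSM1234745-8
GSM1234750	3T9.mycER.RNAseq.4hOHT_2	2/4	RNA-Seq	totRNA	mmu	3T9.mycER	GSM1234745-8
GSM1234751	3T9.mycER.RNAseq.4hOHT_3	3/4	RNA-Seq	totRNA	mmu	3T9.mycER	GSM1234745-8
GSM1234752	3T9.mycER.RNAseq.4hOHT_4	4/4	RNA-Seq	totRNA	mmu	3T9.mycER	GSM1234745-8
GSM1234753	3T9.mycER.RNAseq.8hOHT_1	1/4	RNA-Seq	totRNA	mmu	3T9.mycER	GSM1234745-8
GSM1234754	3T9.mycER.RNAseq.8hOHT_2	2/4	RNA-Seq	totRNA	mmu	3T9.mycER	GSM1234745-8
GSM1234755	3T9.mycER.RNAseq.8hOHT_3	3/4	RNA-Seq	totRNA	mmu	3T9.mycER	GSM1234745-8
GSM1234756	3T9.mycER.RNAseq.8hOHT_4	4/4	RNA-Seq	totRNA	mmu	3T9.mycER	GSM1234745-8
GSM1234757	3T9.mycER.RNAseq.16hOHT_1	1/4	RNA-Seq	totRNA	mmu	3T9.mycER	GSM1234745-8
GSM1234758	3T9.mycER.RNAseq.16hOHT_2	2/4	RNA-Seq	totRNA	mmu	3T9.mycER	GSM1234745-8
GSM1234759	3T9.mycER.RNAseq.16hOHT_3	3/4	RNA-Seq	totRNA	mmu	3T9.mycER	GSM1234745-8
GSM1234760	3T9.mycER.RNAseq.16hOHT_4	4/4	RNA-Seq	totRNA	mmu	3T9.mycER	GSM1234745-8
GSM1234761	3T9.mycER.RNAseq.0hOHT_4sU	1/1	RNA-Seq	4sU-RNA	mmu	3T9.mycER	–
GSM1234762	3T9.mycER.RNAseq.4hOHT_4sU	1/1	RNA-Seq	4sU-RNA	mmu	3T9.mycER	GSM1234761
GSM1230377	3T9.mycER.DNAseI.0hOHT	1/2	DNAse-Seq	–	mmu	3T9.mycER	GSM1230379
GSM1395176	3T9.mycER.DNAseI.0hOHT.B	2/2	DNAse-Seq	–	mmu	3T9.mycER	GSM1230379
GSM1230378	3T9.mycER.DNAseI.4hOHT	1/2	DNAse-Seq	–	mmu	3T9.mycER	GSM1230379
GSM1395177	3T9.mycER.DNAseI.4hOHT.B	2/2	DNAse-Seq	–	mmu	3T9.mycER	GSM1230379
GSM1230379	3T9.mycER.input.DNAseI	1/1	DNAse-Seq	–	mmu	3T9.mycER	–
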