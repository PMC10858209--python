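name	from	to	strand	type
tRNA-Phe	1	68	H
12S	69	1016	H
tRNA-Val(tac)	1017	1088	H
16S	1140	2779	H
tRNA-Leu2(taa)	2788	2862	H
ND1	2863	3837	H
tRNA-Ile (gat)	3842	3911	H
tRNA-Gln (ttg)	3911	3981	L
tRNA-Met(cat)	3981	4049	H
ND2	4050	5096	H
tRNA-Trp (tca)	5097	5167	H
tRNA-Ala (tgc)	5170	5238	L
tRNA-Asn (gtt)	5240	5312	L
OL	5317	5347	H
tRNA-Cys(gca)	5348	5412	L
tRNA-Tyr(gta)	5413	5483	L
COI	5485	7038	H
tRNA-Ser2(tga)	7039	7109	L
tRNA-Asp (gtc)	7113	7184	H
COII	7189	7879	H
tRNA-Lys(ttt)	7880	7955	H
ATP8	7957	8121	H
ATP6	8115	8800	H
COIII	8918	9570	H
tRNA-Gly (tcc)	9585	9656	H
NAD3	9657	10007	H
tRNA-Arg (tcg)	10006	10074	H
NAD4L	10075	10371	H
NAD4	10365	11745	H
tRNA-His (gtg)	11746	11814	H
tRNA-Ser 1(gct)	11815	11882	H
tRNA-Leu1(tag)	11886	11958	H
NAD5	11959	13797	H
NAD6	13794	14318	L
tRNA-Glu (ttc)	14316	14384	L
CYTB	14390	15530	H
tRNA-Thr (tgt)	15531	15603	H
tRNA-Pro (tgg)	15605	15674	L
OH	16170	16500	H
D-loop	15675	16684	H
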