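snp_id	effect_allele	other_allele	eaf	beta	se	pval
rs11130222	A	T	0.59	0.025	0.0023	3.68E-28
rs13090388	T	C	0.31	0.026	0.0024	2.58E-26
rs7029201	A	G	0.41	0.025	0.0023	7.16E-27
rs9401593	A	C	0.52	-0.024	0.0022	3.83E-28
rs12987662	A	C	0.39	0.025	0.0023	8.52E-28
rs8002014	A	G	0.27	-0.024	0.0025	3.80E-21
rs34305371	A	G	0.1	0.036	0.0039	1.52E-20
rs10773002	A	T	0.25	0.022	0.0026	7.74E-18
rs6882046	A	G	0.74	-0.019	0.0025	8.12E-14
rs17824247	T	C	0.59	-0.016	0.0023	2.41E-12
rs61160187	A	G	0.61	-0.017	0.0023	2.71E-14
rs11588857	A	G	0.21	0.02	0.0027	3.27E-13
rs2456973	A	C	0.67	-0.019	0.0024	5.83E-16
rs10786662	C	G	0.55	-0.017	0.0022	4.63E-14
rs4863692	T	G	0.32	0.017	0.0024	4.61E-12
rs10223052	A	G	0.36	0.016	0.0023	3.56E-12
rs11998763	A	G	0.54	0.017	0.0022	4.61E-14
rs9964724	T	C	0.68	0.018	0.0024	2.39E-14
rs6839705	A	C	0.36	0.015	0.0023	1.19E-10
rs7964899	A	G	0.44	0.016	0.0022	4.37E-13
rs12410444	A	G	0.7	-0.017	0.0024	6.01E-13
rs112634398	A	G	0.95	0.038	0.0055	2.74E-12
rs1106761	A	G	0.38	-0.016	0.0023	1.37E-11
rs3172494	T	G	0.12	0.023	0.0036	8.98E-11
rs58694847	C	G	0.26	-0.018	0.0025	4.98E-12
rs1008078	T	C	0.4	-0.017	0.0023	3.10E-14
rs34344888	A	G	0.39	-0.016	0.0023	8.87E-13
rs1378214	T	C	0.37	-0.015	0.0023	1.85E-11
rs16845580	T	C	0.63	0.016	0.0023	4.14E-12
rs12900061	A	G	0.18	0.019	0.0029	5.04E-11
rs35771425	T	C	0.79	0.018	0.0027	2.71E-11
rs7776010	T	C	0.82	-0.021	0.003	2.61E-12
rs1338554	A	G	0.5	0.015	0.0022	1.52E-11
rs356992	C	G	0.3	0.017	0.0024	4.03E-12
rs7593947	A	T	0.51	0.015	0.0022	2.39E-11
rs1912528	T	C	0.36	0.014	0.0023	1.53E-09
rs2992632	A	T	0.72	0.016	0.0025	3.25E-11
rs4741351	A	G	0.3	-0.015	0.0024	2.98E-10
rs6715849	A	G	0.44	-0.015	0.0022	1.65E-11
rs660001	A	G	0.21	-0.018	0.0027	1.34E-10
rs320700	A	G	0.65	0.014	0.0023	3.91E-09
rs113474297	T	C	0.13	-0.021	0.0034	8.34E-10
rs28420834	A	G	0.45	-0.014	0.0023	2.67E-10
rs56231335	T	C	0.67	-0.017	0.0024	7.17E-13
rs62263923	A	G	0.64	-0.017	0.0023	1.11E-13
rs12076635	C	G	0.79	0.018	0.0027	3.11E-11
rs9556958	T	C	0.53	-0.015	0.0022	1.21E-11
rs8049439	T	C	0.59	0.015	0.0023	6.99E-11
rs11774212	T	C	0.52	0.016	0.0023	1.51E-12
rs10483349	A	G	0.81	-0.017	0.0028	7.11E-10
rs71326918	A	C	0.1	0.022	0.0039	1.02E-08
rs11687170	T	C	0.83	0.021	0.0035	1.39E-09
rs7286601	T	G	0.54	-0.014	0.0023	1.99E-09
rs73344830	A	G	0.42	0.015	0.0023	9.93E-12
rs12143094	C	G	0.06	0.029	0.0049	2.73E-09
rs34638686	T	C	0.1	0.023	0.0038	1.51E-09
rs10761741	T	G	0.42	0.013	0.0023	7.05E-09
rs75090987	A	C	0.52	0.014	0.0022	1.14E-09
rs4500960	T	C	0.46	-0.014	0.0022	2.56E-10
rs1562242	T	C	0.48	-0.013	0.0022	5.95E-09
rs192818565	T	G	0.8	0.02	0.0029	2.02E-12
rs12534506	A	T	0.47	-0.014	0.0023	3.17E-10
rs10178115	T	G	0.54	0.014	0.0022	5.84E-10
rs62100765	T	C	0.42	-0.015	0.0023	1.08E-10
rs12142680	A	G	0.09	0.026	0.0043	8.97E-10
rs71413877	A	G	0.04	0.035	0.0058	1.91E-09
rs149613931	T	G	0.06	-0.028	0.0048	5.54E-09
rs17167170	A	G	0.8	0.019	0.0028	1.79E-12
rs12956009	T	C	0.57	-0.013	0.0022	3.75E-09
rs2179152	T	C	0.37	-0.013	0.0023	9.30E-09
rs7033137	C	G	0.76	0.015	0.0026	1.77E-08
rs4378243	T	G	0.83	0.018	0.0029	1.04E-09
rs4493682	C	G	0.17	0.019	0.003	1.54E-10
rs9755467	T	C	0.16	0.019	0.0031	5.11E-10
rs4851251	T	C	0.27	-0.015	0.0025	1.36E-09
rs7945718	A	G	0.62	0.014	0.0023	1.26E-09
rs1382358	T	C	0.87	0.02	0.0035	1.66E-08
rs148490894	A	G	0.98	0.044	0.0078	1.84E-08
rs12761761	T	C	0.24	0.016	0.0027	1.04E-08
rs142328051	T	C	0.91	0.022	0.0039	3.60E-08
rs55786114	T	C	0.07	-0.03	0.0045	4.11E-11
rs7948975	T	C	0.64	0.014	0.0023	1.14E-09
rs1606974	A	G	0.12	0.022	0.0034	1.82E-10
rs10772644	C	G	0.88	0.02	0.0035	1.65E-08
rs111321694	T	C	0.17	-0.016	0.003	4.33E-08
rs17425572	A	G	0.46	0.014	0.0022	1.38E-09
rs111730030	T	G	0.06	-0.029	0.005	7.51E-09
rs1550973	A	G	0.35	-0.014	0.0023	2.00E-09
rs2406253	A	G	0.81	0.016	0.0028	4.64E-08
rs7772172	A	G	0.4	0.013	0.0023	9.83E-09
rs281302	A	G	0.56	-0.013	0.0022	2.88E-09
rs17372140	A	G	0.3	-0.014	0.0024	9.19E-09
rs12640626	A	G	0.58	0.013	0.0023	1.66E-08
rs113011189	T	C	0.09	-0.025	0.0045	2.91E-08
rs56081191	A	G	0.07	0.028	0.0047	3.67E-09
rs12694681	T	G	0.69	0.014	0.0024	1.81E-08
rs12134151	C	G	0.5	-0.013	0.0022	1.14E-08
rs7914680	T	G	0.71	-0.014	0.0025	1.60E-08
rs6493271	T	C	0.83	0.017	0.0029	4.21E-09
rs152603	A	G	0.65	-0.013	0.0023	2.01E-08
rs7791133	A	C	0.38	-0.014	0.0023	2.33E-09
rs1389473	A	G	0.38	-0.013	0.0023	4.52E-09
rs61874768	T	G	0.18	-0.016	0.0029	3.85E-08
rs10818606	T	C	0.4	-0.014	0.0023	5.67E-10
rs2568955	T	C	0.25	-0.016	0.0026	5.77E-10
rs268134	A	G	0.25	0.014	0.0026	3.53E-08
rs6939294	T	C	0.23	0.016	0.0026	2.90E-09
rs12653396	A	T	0.56	-0.013	0.0022	7.65E-09
rs648163	T	C	0.26	0.014	0.0025	1.38E-08
rs140711597	C	G	0.98	0.052	0.0091	1.66E-08
rs301800	T	C	0.18	0.016	0.0029	2.85E-08
rs12462428	T	C	0.81	0.016	0.0028	3.31E-08
rs11756123	A	T	0.35	-0.015	0.0023	6.43E-11
rs7429990	A	C	0.27	-0.015	0.0026	8.44E-09
rs12702087	A	G	0.46	0.013	0.0022	1.74E-09
rs4076457	T	C	0.25	0.015	0.0026	8.85E-09
rs78387210	T	C	0.09	0.023	0.004	8.41E-09
rs7610856	A	C	0.43	0.012	0.0023	3.02E-08
rs78365243	T	C	0.95	0.029	0.0052	2.22E-08
rs1115240	C	G	0.75	-0.016	0.0026	7.05E-10
rs7605827	A	T	0.29	0.016	0.0029	4.86E-08
rs76076331	T	C	0.14	0.02	0.0032	2.38E-10
rs1596747	A	G	0.51	0.014	0.0022	1.14E-09
rs77702819	T	G	0.09	0.022	0.004	2.93E-08
rs12646808	T	C	0.66	0.015	0.0024	3.79E-10
rs2624818	A	G	0.11	0.021	0.0037	8.63E-09
rs7633857	C	G	0.52	-0.014	0.0026	4.74E-08
rs11976020	A	G	0.23	-0.015	0.0027	4.43E-08
rs4308415	C	G	0.44	-0.013	0.0022	2.52E-09
rs700590	T	C	0.59	-0.013	0.0023	2.84E-08
rs756912	T	C	0.52	-0.014	0.0022	1.14E-09
rs7241530	T	C	0.36	-0.013	0.0023	2.28E-08
rs35971989	A	G	0.84	0.018	0.0032	2.95E-08
rs11771168	T	C	0.24	-0.015	0.0027	2.56E-08
rs17504614	T	C	0.8	0.016	0.0028	1.56E-08
rs9914544	A	C	0.62	-0.013	0.0023	4.66E-08
rs4675248	A	G	0.4	-0.012	0.0023	4.39E-08
rs6800916	A	T	0.08	-0.024	0.0043	1.70E-08
rs35532491	A	T	0.9	-0.022	0.0038	7.15E-09
rs56044892	T	C	0.2	-0.016	0.0028	5.37E-09
rs79925071	T	G	0.56	0.013	0.0022	1.52E-08
rs12145291	T	C	0.94	-0.029	0.0051	2.21E-08
rs34106693	C	G	0.83	0.017	0.0031	1.80E-08
rs12754946	T	C	0.57	0.013	0.0023	1.48E-08
rs4741343	A	G	0.18	-0.016	0.0029	2.32E-08
rs76878669	C	G	0.76	0.014	0.0026	4.12E-08
rs775326	A	C	0.32	-0.014	0.0024	1.22E-08
rs10821136	T	C	0.34	0.013	0.0024	3.58E-08
rs1925576	A	G	0.54	-0.012	0.0022	2.23E-08
rs6065080	T	C	0.36	-0.013	0.0023	1.16E-08
rs56158183	A	G	0.07	0.025	0.0043	1.42E-08
rs12531458	A	C	0.52	0.012	0.0022	3.81E-08
rs62379838	T	C	0.69	0.013	0.0024	4.06E-08
rs7590368	T	C	0.73	-0.014	0.0025	2.72E-08
rs113520408	A	G	0.27	0.015	0.0025	7.15E-09
rs62263033	T	C	0.96	0.037	0.0063	5.60E-09
rs11643654	A	C	0.6	0.013	0.0023	2.00E-08
rs10930008	A	G	0.73	-0.014	0.0025	4.14E-08
rs56262138	A	T	0.3	0.014	0.0025	2.29E-08
rs113779084	A	G	0.31	0.014	0.0024	2.70E-08
rs62262721	T	C	0.96	0.042	0.0072	3.41E-09
rs1967109	A	G	0.15	-0.017	0.0031	4.40E-08
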