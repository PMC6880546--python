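cpg	weight	set
cg93551893	-0.30662	dnamalc.5
cg52537052	0.525454	dnamalc.5
cg31018273	-2.150412	dnamalc.5
cg09795107	-0.149842	dnamalc.5
cg51185038	2.688602	dnamalc.5
cg93551893	-0.30662	dnamalc.23
cg52537052	0.525454	dnamalc.23
cg31018273	-2.150412	dnamalc.23
cg09795107	-0.149842	dnamalc.23
cg51185038	2.688602	dnamalc.23
cg44270008	0.46356	dnamalc.23
cg48235168	-0.376615	dnamalc.23
cg24767894	0.42132	dnamalc.23
cg31454973	-1.589617	dnamalc.23
cg01989563	0.278932	dnamalc.23
cg91586373	8.73401	dnamalc.23
cg02222847	-1.230283	dnamalc.23
cg96245034	1.040279	dnamalc.23
cg47058180	0.6615	dnamalc.23
cg29619953	-0.51063	dnamalc.23
cg14813201	0.419302	dnamalc.23
cg35726638	-1.12015	dnamalc.23
cg56604452	-0.703582	dnamalc.23
cg21697533	-2.309465	dnamalc.23
cg50752496	0.109218	dnamalc.23
cg95431157	-0.835853	dnamalc.23
cg23793133	-0.721289	dnamalc.23
cg51371360	1.171093	dnamalc.23
cg93551893	-0.30662	dnamalc.78
cg52537052	0.525454	dnamalc.78
cg31018273	-2.150412	dnamalc.78
cg09795107	-0.149842	dnamalc.78
cg51185038	2.688602	dnamalc.78
cg44270008	0.46356	dnamalc.78
cg48235168	-0.376615	dnamalc.78
cg24767894	0.42132	dnamalc.78
cg31454973	-1.589617	dnamalc.78
cg01989563	0.278932	dnamalc.78
cg91586373	8.73401	dnamalc.78
cg02222847	-1.230283	dnamalc.78
cg96245034	1.040279	dnamalc.78
cg47058180	0.6615	dnamalc.78
cg29619953	-0.51063	dnamalc.78
cg14813201	0.419302	dnamalc.78
cg35726638	-1.12015	dnamalc.78
cg56604452	-0.703582	dnamalc.78
cg21697533	-2.309465	dnamalc.78
cg50752496	0.109218	dnamalc.78
cg95431157	-0.835853	dnamalc.78
cg23793133	-0.721289	dnamalc.78
cg51371360	1.171093	dnamalc.78
cg84739003	0.09198	dnamalc.78
cg34411219	-4.706329	dnamalc.78
cg60608442	0.58795	dnamalc.78
cg41058805	6.43025	dnamalc.78
cg35101969	1.643369	dnamalc.78
cg34697295	0.287383	dnamalc.78
cg26743029	-1.114213	dnamalc.78
cg28629712	1.272248	dnamalc.78
cg73655045	1.259822	dnamalc.78
cg73068809	1.178202	dnamalc.78
cg62378355	1.24748	dnamalc.78
cg35394880	0.523132	dnamalc.78
cg08325507	-0.905571	dnamalc.78
cg80837816	2.963963	dnamalc.78
cg29531396	-0.600864	dnamalc.78
cg08014027	-0.433108	dnamalc.78
cg79435535	-1.886149	dnamalc.78
cg86440073	-2.507086	dnamalc.78
cg53221619	0.932504	dnamalc.78
cg42768902	1.211861	dnamalc.78
cg39916635	-0.544258	dnamalc.78
cg94204871	-1.709075	dnamalc.78
cg78073457	1.021289	dnamalc.78
cg94483428	-1.524262	dnamalc.78
cg58799354	-2.029926	dnamalc.78
cg45296633	0.315215	dnamalc.78
cg79024957	-1.533566	dnamalc.78
cg16737807	1.129974	dnamalc.78
cg62481651	2.587112	dnamalc.78
cg81785747	1.1372	dnamalc.78
cg79971100	2.283111	dnamalc.78
cg04071764	-3.624473	dnamalc.78
cg11974601	1.593389	dnamalc.78
cg39345977	1.312822	dnamalc.78
cg71946093	-3.235617	dnamalc.78
cg03966673	0.812048	dnamalc.78
cg14210165	-1.68253	dnamalc.78
cg09077360	1.461787	dnamalc.78
cg40403277	0.061338	dnamalc.78
cg33915741	0.314634	dnamalc.78
cg13403146	-2.124816	dnamalc.78
cg69672312	0.951606	dnamalc.78
cg26469422	-0.166882	dnamalc.78
cg98319756	0.209284	dnamalc.78
cg87824503	-0.865274	dnamalc.78
cg34654351	0.062709	dnamalc.78
cg13505985	-2.078353	dnamalc.78
cg91947473	-0.348866	dnamalc.78
cg55375832	1.826609	dnamalc.78
cg47822170	0.16687	dnamalc.78
cg78220165	-0.265661	dnamalc.78
cg88163844	-0.77342	dnamalc.78
cg49751788	-2.140755	dnamalc.78
cg55154352	0.360325	dnamalc.78
cg98442999	3.002695	dnamalc.78
cg93551893	-0.30662	dnamalc.144
cg52537052	0.525454	dnamalc.144
cg31018273	-2.150412	dnamalc.144
cg09795107	-0.149842	dnamalc.144
cg51185038	2.688602	dnamalc.144
cg44270008	0.46356	dnamalc.144
cg48235168	-0.376615	dnamalc.144
cg24767894	0.42132	dnamalc.144
cg31454973	-1.589617	dnamalc.144
cg01989563	0.278932	dnamalc.144
cg91586373	8.73401	dnamalc.144
cg02222847	-1.230283	dnamalc.144
cg96245034	1.040279	dnamalc.144
cg47058180	0.6615	dnamalc.144
cg29619953	-0.51063	dnamalc.144
cg14813201	0.419302	dnamalc.144
cg35726638	-1.12015	dnamalc.144
cg56604452	-0.703582	dnamalc.144
cg21697533	-2.309465	dnamalc.144
cg50752496	0.109218	dnamalc.144
cg95431157	-0.835853	dnamalc.144
cg23793133	-0.721289	dnamalc.144
cg51371360	1.171093	dnamalc.144
cg84739003	0.09198	dnamalc.144
cg34411219	-4.706329	dnamalc.144
cg60608442	0.58795	dnamalc.144
cg41058805	6.43025	dnamalc.144
cg35101969	1.643369	dnamalc.144
cg34697295	0.287383	dnamalc.144
cg26743029	-1.114213	dnamalc.144
cg28629712	1.272248	dnamalc.144
cg73655045	1.259822	dnamalc.144
cg73068809	1.178202	dnamalc.144
cg62378355	1.24748	dnamalc.144
cg35394880	0.523132	dnamalc.144
cg08325507	-0.905571	dnamalc.144
cg80837816	2.963963	dnamalc.144
cg29531396	-0.600864	dnamalc.144
cg08014027	-0.433108	dnamalc.144
cg79435535	-1.886149	dnamalc.144
cg86440073	-2.507086	dnamalc.144
cg53221619	0.932504	dnamalc.144
cg42768902	1.211861	dnamalc.144
cg39916635	-0.544258	dnamalc.144
cg94204871	-1.709075	dnamalc.144
cg78073457	1.021289	dnamalc.144
cg94483428	-1.524262	dnamalc.144
cg58799354	-2.029926	dnamalc.144
cg45296633	0.315215	dnamalc.144
cg79024957	-1.533566	dnamalc.144
cg16737807	1.129974	dnamalc.144
cg62481651	2.587112	dnamalc.144
cg81785747	1.1372	dnamalc.144
cg79971100	2.283111	dnamalc.144
cg04071764	-3.624473	dnamalc.144
cg11974601	1.593389	dnamalc.144
cg39345977	1.312822	dnamalc.144
cg71946093	-3.235617	dnamalc.144
cg03966673	0.812048	dnamalc.144
cg14210165	-1.68253	dnamalc.144
cg09077360	1.461787	dnamalc.144
cg40403277	0.061338	dnamalc.144
cg33915741	0.314634	dnamalc.144
cg13403146	-2.124816	dnamalc.144
cg69672312	0.951606	dnamalc.144
cg26469422	-0.166882	dnamalc.144
cg98319756	0.209284	dnamalc.144
cg87824503	-0.865274	dnamalc.144
cg34654351	0.062709	dnamalc.144
cg13505985	-2.078353	dnamalc.144
cg91947473	-0.348866	dnamalc.144
cg55375832	1.826609	dnamalc.144
cg47822170	0.16687	dnamalc.144
cg78220165	-0.265661	dnamalc.144
cg88163844	-0.77342	dnamalc.144
cg49751788	-2.140755	dnamalc.144
cg55154352	0.360325	dnamalc.144
cg98442999	3.002695	dnamalc.144
cg08885405	-0.173592	dnamalc.144
cg38983856	2.112368	dnamalc.144
cg26222575	-0.146051	dnamalc.144
cg05870502	-4.626349	dnamalc.144
cg39687184	-0.198435	dnamalc.144
cg60460442	-1.831916	dnamalc.144
cg31612084	-0.076616	dnamalc.144
cg03100473	-0.210656	dnamalc.144
cg64910472	-1.288542	dnamalc.144
cg27535780	-2.312185	dnamalc.144
cg02390494	-0.349089	dnamalc.144
cg64351103	3.351311	dnamalc.144
cg93665411	-0.078369	dnamalc.144
cg61328358	-2.609931	dnamalc.144
cg87002515	-0.610873	dnamalc.144
cg75150031	1.051275	dnamalc.144
cg84129451	-0.653076	dnamalc.144
cg70300401	0.361776	dnamalc.144
cg75752678	0.166151	dnamalc.144
cg14850710	6.504137	dnamalc.144
cg88079643	-1.694587	dnamalc.144
cg62037022	0.788671	dnamalc.144
cg50306845	-1.954673	dnamalc.144
cg51761069	0.19651	dnamalc.144
cg62335037	4.329752	dnamalc.144
cg39583717	0.561407	dnamalc.144
cg36304073	-0.326356	dnamalc.144
cg92603392	-1.66453	dnamalc.144
cg68745517	0.363208	dnamalc.144
cg85670261	1.660522	dnamalc.144
cg41220989	-2.69875	dnamalc.144
cg32369029	-0.711017	dnamalc.144
cg02466522	-0.507233	dnamalc.144
cg48192562	4.083976	dnamalc.144
cg15146929	2.842888	dnamalc.144
cg32910860	-0.482935	dnamalc.144
cg06135612	0.392908	dnamalc.144
cg78321804	2.821977	dnamalc.144
cg04792617	0.827409	dnamalc.144
cg25867700	-0.253111	dnamalc.144
cg54197926	2.591953	dnamalc.144
cg91195676	0.221661	dnamalc.144
cg92728782	-5.885499	dnamalc.144
cg95223677	-1.066362	dnamalc.144
cg12348160	0.227888	dnamalc.144
cg46414094	0.242905	dnamalc.144
cg18152705	0.54428	dnamalc.144
cg55135353	-1.503078	dnamalc.144
cg53570269	1.541352	dnamalc.144
cg33854078	-0.288829	dnamalc.144
cg38931885	0.611917	dnamalc.144
cg59855493	0.82378	dnamalc.144
cg07362612	-0.227533	dnamalc.144
cg07446279	0.171633	dnamalc.144
cg56430610	-3.14788	dnamalc.144
cg85762162	3.562171	dnamalc.144
cg52532719	-3.651704	dnamalc.144
cg91696539	0.710959	dnamalc.144
cg09480736	-0.562534	dnamalc.144
cg07698005	-3.975264	dnamalc.144
cg92998722	3.713867	dnamalc.144
cg36216848	0.072077	dnamalc.144
cg64373418	-0.178862	dnamalc.144
cg96266398	5.748832	dnamalc.144
cg88960314	0.579313	dnamalc.144
cg05647267	2.474207	dnamalc.144
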