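# Myopia susceptibility SNP panel: rs IDs at loci implicated by genetic
# linkage studies (source=linkage) and genome-wide association studies
# (source=gwas) of (pathological) myopia.
# columns: rs_id <tab> gene <tab> locus <tab> source
rs1034762	MYP2	18p11.31	linkage
rs1635529	MYP2	18p11.31	linkage
rs1793933	MYP2	18p11.31	linkage
rs3803183	MYP2	18p11.31	linkage
rs17122571	MYP2	18p11.31	linkage
rs3832846	MYP3	12q21-q23	linkage
rs17853500	MYP3	12q21-q23	linkage
rs3759223	MYP3	12q21-q23	linkage
rs10860860	MYP3	12q21-q23	linkage
rs2946834	MYP3	12q21-q23	linkage
rs6214	MYP3	12q21-q23	linkage
rs1506	MYP7	11p13	linkage
rs592859	MYP7	11p13	linkage
rs608293	MYP7	11p13	linkage
rs628224	MYP7	11p13	linkage
rs662702	MYP7	11p13	linkage
rs667773	MYP7	11p13	linkage
rs694617	MYP7	11p13	linkage
rs1540320	MYP7	11p13	linkage
rs1806155	MYP7	11p13	linkage
rs1806158	MYP7	11p13	linkage
rs1806159	MYP7	11p13	linkage
rs1806180	MYP7	11p13	linkage
rs1894620	MYP7	11p13	linkage
rs2071754	MYP7	11p13	linkage
rs2239789	MYP7	11p13	linkage
rs3026389	MYP7	11p13	linkage
rs3026401	MYP7	11p13	linkage
rs113432966	MYP11	4q22-q27	linkage
rs112669274	MYP11	4q22-q27	linkage
rs112391551	MYP11	4q22-q27	linkage
rs112356377	MYP11	4q22-q27	linkage
rs111691784	MYP11	4q22-q27	linkage
rs111322719	MYP11	4q22-q27	linkage
rs111706042	MYP12	2q37.1	linkage
rs113695792	MYP13	Xq23-q25	linkage
rs111774596	MYP13	Xq23-q25	linkage
rs113328794	MYP14	1p36	linkage
rs121909066	TGIF	18p11.31	linkage
rs121909067	TGIF	18p11.31	linkage
rs121909068	TGIF	18p11.31	linkage
rs121909069	TGIF	18p11.31	linkage
rs121909070	TGIF	18p11.31	linkage
rs28939693	TGIF	18p11.31	linkage
rs634990	GJD2	15q14	gwas
rs939661	RASGRF1	15q25	gwas
rs6885224	CTNND2	5q15	gwas
rs12716080	CTNND2	5q15	gwas
rs9318086	MIPEP	13q12.12	gwas
rs4373767	ZC3H11B	1q41	gwas
rs12193446	LAMA2	6q22.33	gwas
rs1572275	CD55	1q32.2	gwas
rs6680123	ZNF644	1p22.2	gwas
rs10034228	MYP11	4q25	gwas
rs1585471	MYP11	4q25	gwas
rs577948	BLID	11q24.1	gwas
rs12275397	GLULP3	.	gwas
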