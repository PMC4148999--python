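phylum	type_strains	species_subsp	type_genomes	nontype_genomes	proposed
Crenarchaeota	57	61	33	0	0
Euryarchaeota	314	388	143	4	9
Thaumarchaeota	1	1	1	0	0
Aquificae	29	31	8	0	2
Thermotogae	37	38	14	1	13
Thermodesulfobacteria	7	8	2	1	4
Deinococcus-Thermus	71	76	19	0	18
Chrysiogenetes	4	4	2	0	0
Chloroflexi	27	28	11	0	0
Nitrospirae	12	12	2	0	3
Deferribacteres	12	12	6	0	1
Cyanobacteria	88	90	9	2	0
Chlorobi	16	22	9	0	0
Proteobacteria	3541	4323	364	35	385
Firmicutes	1875	2263	311	14	285
Tenericutes	234	258	25	0	2
Actinobacteria	2439	2953	145	5	129
Planctomycetes	15	19	10	0	2
Chlamydiae	17	20	8	0	0
Spirochaetes	112	127	25	0	2
Fibrobacteres	3	5	1	0	0
Acidobacteria	11	11	3	0	0
Bacteroidetes	767	914	131	9	134
Fusobacteria	38	47	12	0	7
Verrucomicrobia	35	35	6	2	3
Gemmatimonadetes	1	1	1	0	0
Dictyoglomi	2	3	2	0	0
Lentisphaerae	2	2	1	0	0
Synergistetes	17	18	10	1	1
Caldiserica	1	1	1	0	0
Elusimicrobia	1	1	1	0	0
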