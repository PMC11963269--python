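# Literature-derived reference table: structural characteristics of 63 Retand
# PRARE clusters (copy number, mean LTR / internal-region / POL-3'LTR sizes in
# bp, core-domain presence, TRP28 status, extra antisense-ORF domains, tandem
# array counts). trp28 values: YES, NO, or SHORT (domain present but only in an
# ORF shorter than 600 nt). Sizes are per-cluster averages over member elements.
group	cluster	copy_number	ltr_bp	internal_bp	pol3ltr_bp	gag	ap	rh	int	trp28	other_domains	tandem_arrays
Liliopsida 1	Alopecurus myosuroides 7c	26	477	9671	5427	NO	YES	YES	YES	YES	-	0
Liliopsida 1	Alopecurus myosuroides 7b	23	481	9685	5433	NO	YES	YES	YES	YES	-	0
Liliopsida 1	Alopecurus myosuroides 7a	13	479	9680	5428	NO	YES	YES	YES	YES	-	0
Liliopsida 1	Alopecurus myosuroides 7j	180	454	9480	5305	NO	YES	YES	YES	YES	-	0
Liliopsida 1	Alopecurus myosuroides 7i	52	454	9581	5279	NO	YES	YES	YES	YES	-	0
Liliopsida 1	Aegilops umbellulata 1	33	504	12140	5663	YES	YES	YES	YES	YES	-	1
Liliopsida 1	Secale cereale 1	10	506	12869	6091	YES	YES	YES	YES	YES	-	1
Liliopsida 1	Secale cereale 2	26	507	12726	6153	YES	YES	YES	YES	YES	-	1
Liliopsida 1	Avena atlantica 1	37	491	11237	4743	YES	YES	YES	YES	YES	DNA-topo2	1
Liliopsida 1	Alopecurus myosuroides 3a	46	576	10798	3906	YES	NO	YES	YES	YES	-	0
Liliopsida 1	Alopecurus myosuroides 3b	43	577	8734	4079	YES	YES	NO	NO	YES	-	0
Liliopsida 1	Alopecurus myosuroides 2	55	564	8734	4102	YES	YES	NO	NO	YES	-	0
Liliopsida 1	Triticum aestivum 10	10	528	11996	5828	YES	YES	YES	YES	YES	-	1
Liliopsida 1	Poa annua 1b	10	424	12250	5501	YES	YES	YES	YES	YES	-	2
Liliopsida 1	Poa annua 1a	15	439	12029	5301	YES	YES	YES	YES	YES	-	2
Liliopsida 1	Alopecurus myosuroides 5c	133	491	11821	5491	YES	YES	YES	YES	YES	-	0
Liliopsida 1	Alopecurus myosuroides 5b	15	493	11834	5474	YES	NO	YES	YES	YES	-	0
Liliopsida 1	Saccharum spontaneum 1a	10	1065	12304	5854	YES	YES	YES	YES	YES	polIII	0
Liliopsida 1	Oryza rufipogon 2	18	440	10428	4282	YES	YES	YES	YES	YES	-	0
Liliopsida 2	Oryza rufipogon 1d	35	1077	10727	4484	YES	YES	YES	YES	YES	Smc	0
Liliopsida 2	Oryza rufipogon 1c	61	1174	10703	4483	YES	YES	YES	YES	YES	Smc	0
Liliopsida 2	Secale cereale 5b	21	947	11752	5367	YES	YES	YES	YES	YES	Smc/polIII	0
Liliopsida 2	Secale cereale 5a	65	954	11775	5359	YES	YES	YES	YES	YES	Smc/polIII	2
Liliopsida 2	Poa annua 4b	21	1031	10962	4981	YES	YES	YES	YES	YES	Smc/polIII	0
Liliopsida 2	Poa annua 4a	24	1079	10861	4914	YES	YES	YES	YES	YES	-	0
Liliopsida 3	Zea mays 2	12	585	8245	4200	NO	YES	YES	YES	YES	-	0
Liliopsida 3	Zea mays 1	21	587	8365	4313	NO	NO	YES	YES	YES	-	1
Eudicot 1	Artemisia tridentata 2a	63	488	9588	3868	YES	YES	YES	YES	YES	-	0
Eudicot 1	Artemisia tridentata 1	42	488	9581	3899	YES	YES	YES	YES	YES	-	0
Eudicot 1	Artemisia argyi 1	81	496	9362	3665	YES	YES	YES	YES	YES	-	0
Eudicot 1	Glebionis coronaria 2b	13	571	9588	4035	YES	NO	YES	YES	YES	-	0
Eudicot 1	Glebionis coronaria 2a	41	581	9843	4108	YES	NO	YES	YES	YES	-	0
Eudicot 1	Helianthus annuus 3a	23	880	10274	4549	YES	YES	YES	YES	YES	-	1
Eudicot 1	Helianthus annuus 2	15	806	11456	5899	YES	YES	YES	YES	YES	TolA	0
Eudicot 1	Salvia splendens 1	23	597	9719	4234	YES	YES	YES	YES	YES	-	1
Eudicot 2	Medicago ruthenica 1	19	315	7380	3888	NO	NO	YES	YES	YES	-	0
Eudicot 2	Lotus japonicus 1	47	378	8780	3281	YES	YES	YES	YES	YES	-	0
Eudicot 2	Comarum palustre 1	63	483	9994	4340	YES	YES	YES	YES	YES	-	3
Eudicot 2	Spinacia oleracea 1	54	425	10719	4850	YES	YES	YES	YES	YES	-	1
Eudicot 2	Ballota nigra 5a	28	775	10294	4118	YES	YES	YES	YES	YES	-	0
Eudicot 2	Ballota nigra 3	28	685	10371	4252	YES	YES	YES	YES	YES	-	0
Eudicot 2	Ballota nigra 2a	19	737	10519	4282	YES	YES	YES	YES	YES	Smc	0
Eudicot 2	Ballota nigra 1	12	696	9557	3609	YES	YES	YES	YES	YES	Recom.Inh.	1
Eudicot 2	Apium graveolens 1b	24	569	9357	3801	YES	YES	YES	YES	YES	-	2
Eudicot 2	Apium graveolens 1a	41	548	9753	4121	YES	YES	YES	YES	YES	-	2
Eudicot 2	Apium graveolens 2a	10	570	9626	3997	YES	YES	YES	YES	YES	-	3
Eudicot 2	Heracleum sosnowskyi 2a	16	504	10937	3492	YES	YES	YES	YES	YES	-	1
Eudicot 2	Heracleum sosnowskyi 1	38	504	9198	3459	YES	YES	YES	YES	YES	-	2
Eudicot 2	Chamaenerion angustifolium 2	171	664	10051	4522	YES	YES	YES	YES	YES	-	1
Eudicot 2	Sambucus nigra 4	76	586	10964	4895	YES	YES	YES	YES	SHORT	-	1
Eudicot 2	Sambucus nigra 2	29	586	10938	4954	YES	YES	YES	YES	SHORT	-	1
Eudicot 2	Sambucus nigra 3	68	586	10943	4953	YES	YES	YES	YES	SHORT	-	1
Eudicot 2	Sambucus nigra 6	39	857	10861	4771	YES	YES	YES	YES	YES	-	1
Eudicot 2	Camellia oleifera 2	13	551	10377	4812	YES	YES	YES	YES	YES	Smc	2
Eudicot 2	Nyssa sinensis 1	15	627	10468	4582	YES	YES	YES	YES	YES	-	2
Eudicot 2	Dimocarpus longan 1	10	713	9540	3682	YES	YES	YES	YES	YES	Smc	0
Eudicot 2	Camellia sinensis 4	18	824	10483	4472	YES	YES	YES	YES	SHORT	-	1
Eudicot 2	Camellia oleifera 1	23	584	9983	4290	YES	NO	YES	YES	SHORT	-	1
Eudicot 2	Centaurea solstitialis 2a	58	900	8485	2933	YES	YES	YES	YES	YES	-	1
Eudicot 2	Helianthus annuus 5	12	719	9313	3343	YES	YES	YES	YES	NO	-	2
Eudicot 2	Helianthus annuus 4	7	720	9310	3327	YES	YES	YES	YES	NO	-	2
Liliopsida/Eudicot	Rhynchospora pubera 3	12	432	11818	5552	YES	YES	YES	YES	YES	-	3
Liliopsida/Eudicot	Linaria vulgaris 1	22	1194	12114	6556	YES	YES	YES	YES	YES	-	0
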