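taxonomic_level	sample_group	n_genera	n_samples	n_paralogous_loci	n_non_paralogous_loci
tribe	Vernonieae	19	26	636	174
genus	Lychnophora	1	6	485	482
genus	Chresta	1	6	389	432
tribe	Heliantheae	7	13	500	238
genus	Helianthus	1	4	348	702
genus	Lipochaeta	1	3	376	419
tribe	Cardueae	5	14	267	465
genus	Cousinia	1	5	250	702
species	Carlina vulgaris	1	6	190	658
tribe	Senecioneae	5	16	590	401
genus	Pericallis	1	6	476	404
genus	Senecio	1	7	544	306
tribe	Gnaphalieae	8	11	477	240
genus	Antennaria	1	4	424	452
tribe	Cichorieae	9	30	721	212
genus	Sonchus	1	4	341	680
genus	Lactuca	1	6	520	524
species_complex	Picris hieracioides complex	1	9	376	610
species	Hieracium alpinum	1	6	370	647
species	Picris hieracioides	1	5	371	664
tribe	Moquinieae	2	2	461	547
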