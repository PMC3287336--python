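order	family	species	P. austriacus	P. auritus	confidence
Lepidoptera	Aractiidae	Unknown	2	0	3
Lepidoptera	Aractiidae	Diaphora mendica	1	0	1
Lepidoptera	Aractiidae	Seirarctia sp.	1	0	1
Lepidoptera	Aractiidae	Spilosoma luteum	3	0	1
Lepidoptera	Crambidae	Agriphila tristella	2	0	1
Lepidoptera	Crambidae	Chrysoteuchia culmella	2	0	2
Lepidoptera	Crambidae	Crambus perlella	1	0	2
Lepidoptera	Elachistidae	Depressaria daucella	1	0	1
Lepidoptera	Elachistidae	Semioscopis sp.	2	0	1
Lepidoptera	Gelechiidae	Carpatolechia decorella	1	2	1
Lepidoptera	Geometridae	Gymnoscelis rufifasciata	1	0	2
Lepidoptera	Hepialidae	Hepialus sp.	6	2	2
Lepidoptera	Hepialidae	Hepialus sylvina	6	3	1
Lepidoptera	Noctuidae	Unknown	6	3	3
Lepidoptera	Noctuidae	Acronicta alni	0	1	1
Lepidoptera	Noctuidae	Agrochola litura	0	1	1
Lepidoptera	Noctuidae	Agrochola lota	0	1	1
Lepidoptera	Noctuidae	Agrochola lychnidis	0	1	2
Lepidoptera	Noctuidae	Agrochola macilenta	0	1	1
Lepidoptera	Noctuidae	Agrotis exclamationis	4	2	1
Lepidoptera	Noctuidae	Agrotis ipsilon	2	0	2
Lepidoptera	Noctuidae	Agrotis segetum	1	0	1
Lepidoptera	Noctuidae	Agrotis puta	1	0	1
Lepidoptera	Noctuidae	Allophyes oxyacanthae	1	2	2
Lepidoptera	Noctuidae	Apamea crenata	0	1	1
Lepidoptera	Noctuidae	Apamea epomidion	0	1	1
Lepidoptera	Noctuidae	Apamea monoglypha	6	0	2
Lepidoptera	Noctuidae	Apamea sp.	1	0	1
Lepidoptera	Noctuidae	Autographa gamma	11	2	1
Lepidoptera	Noctuidae	Charanyca trigrammica	1	0	2
Lepidoptera	Noctuidae	Conistra sp.	0	1	2
Lepidoptera	Noctuidae	Diarsia sp.	0	2	2
Lepidoptera	Noctuidae	Hoplodrina ambigua	1	0	1
Lepidoptera	Noctuidae	Hydraecia micacea	1	0	2
Lepidoptera	Noctuidae	Hydraecia sp.	1	0	1
Lepidoptera	Noctuidae	Hypena proboscidalis	0	1	1
Lepidoptera	Noctuidae	Lithophane hepatica	1	0	2
Lepidoptera	Noctuidae	Mythimna albipuncta	2	0	1
Lepidoptera	Noctuidae	Mythimna pallens	0	1	2
Lepidoptera	Noctuidae	Noctua comes	2	0	2
Lepidoptera	Noctuidae	Noctua pronuba	19	13	1
Lepidoptera	Noctuidae	Noctua sp.	1	1	2
Lepidoptera	Noctuidae	Ochropleura sp.	0	1	2
Lepidoptera	Noctuidae	Oligia sp.	0	1	1
Lepidoptera	Noctuidae	Omphaloscelis lunosa	1	1	1
Lepidoptera	Noctuidae	Orthosia gothica	1	0	2
Lepidoptera	Noctuidae	Phlogophora meticulosa	2	0	1
Lepidoptera	Noctuidae	Scoliopteryx libatrix	1	0	1
Lepidoptera	Noctuidae	Tholera cespitis	0	1	1
Lepidoptera	Noctuidae	Tholera decimalis	2	0	1
Lepidoptera	Noctuidae	Xestia xanthographa	2	6	2
Lepidoptera	Oecophoridae	Diurnea fagella	0	1	2
Lepidoptera	Oecophoridae	Endrosis sarcitrella	0	1	2
Diptera	Anisopodidae	Unknown	0	1	3
Diptera	Calliphoridae	Unknown	0	1	3
Diptera	Calliphoridae	Pollenia sp.	0	1	2
Diptera	Muscidae	Unknown	0	2	3
Diptera	Muscidae	Eudasyphora cyanella	1	2	1
Diptera	Muscidae	Eudasyphora sp.	0	1	1
Diptera	Muscidae	Helina impuncta	1	0	1
Diptera	Muscidae	Morellia simplex	0	1	1
Diptera	Muscidae	Phaonia subventa	1	3	1
Diptera	Muscidae	Polietes lardarius	0	3	1
Diptera	Scathophagidae	Scathophaga stercoraria	1	1	1
Diptera	Syrphidae	Platycheirus sp.	0	2	2
Diptera	Tachinidae	Leskia sp.	1	4	1
Diptera	Tipulidae	Unknown	1	0	3
Diptera	Tipulidae	Tipula oleracea	8	1	1
Diptera	Tipulidae	Tipula sp.	1	0	1
Neuroptera	Chrysopidae	Unknown	2	0	3
Coleoptera	Dermestidae	Anthrenus fuscus	0	1	1
Hemiptera	Miridae	Unknown	3	0	3
Hemiptera	Miridae	Phytocoris tiliae	1	0	1
Trichoptera	Limnephilidae	Stenophylax sp.	1	0	2
Isopoda	Porcellionidae	Porcellio scaber	1	1	1
Isopoda	Porcellionidae	Porcellio sp.	0	1	1
Araneae	Anyphaenidae	Unknown	0	1	3
Araneae	Anyphaenidae	Anyphaena accentuata	0	1	1
Araneae	Tetragnathidae	Metellina segmentata	0	1	1
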