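sample_id	order	family	genus	site	ffg
LEWI-A1	Diptera	Ceratopogonidae	NA	LEWI	Predators
LEWI-A2	Diptera	Tabanidae	NA	LEWI	Predators
MCRA-A11	Ephemeroptera	Heptageniidae	Epeorus	MCRA	Scrapers
MCRA-A12	Plecoptera	Perlidae	NA	MCRA	Predators
MCRA-A13	Trichoptera	Hydropsychidae	NA	MCRA	Filtering collectors
MCRA-A15	Ephemeroptera	Ameletidae	Ameletus	MCRA	Gathering collectors
BLUE-A21	Diptera	Chironomidae	NA	BLUE	Filtering collectors
BLUE-A22	Coleoptera	Elmidae	Stenelmis	BLUE	Gathering collectors
BLUE-A23	Ephemeroptera	Ephemeridae	Ephemera	BLUE	Scrapers
BLUE-A24	Ephemeroptera	Heptageniidae	Leucrocuta	BLUE	Scrapers
BLUE-A25	Megaloptera	Corydalidae	Corydalus	BLUE	Predators
MCDI-A31	Diptera	Simuliidae	Simulium	MCDI	Filtering collectors
MCDI-A32	Diptera	Tipulidae	Tipula	MCDI	Predators
MCDI-A33	Ephemeroptera	Heptageniidae	Stenonema	MCDI	Scrapers
MCDI-A34	Trichoptera	Hydropsychidae	Cheumatopsyche	MCDI	Filtering collectors
MCDI-A35	Ephemeroptera	Baetidae	Fallceon	MCDI	Gathering collectors
HOPB-A41	Trichoptera	Hydropsychidae	Cheumatopsyche	HOPB	Filtering collectors
HOPB-A42	Trichoptera	Glossosomatidae	Glossosoma	HOPB	Scrapers
HOPB-A43	Ephemeroptera	Heptageniidae	Maccaffertium	HOPB	Scrapers
HOPB-A44	Ephemeroptera	Leptophlebiidae	Paraleptophlebia	HOPB	Gathering collectors
BLDE-A51	Trichoptera	Brachycentridae	Micrasema	BLDE	Gathering collectors
BLD3-A52	Ephemeroptera	Baetidae	Acentrella	BLDE	Gathering collectors
BLDE-A53	Diptera	Psychodidae	Pericoma	BLDE	Gathering collectors
BLDE-A54	Plecoptera	Chloroperlidae	Sweltsa	BLDE	Predators
LECO-A61	Diptera	Dixidae	Dixa	LECO	Filtering collectors
LECO-A62	Coleoptera	Ptilodactylidae	Anchytarsus	LECO	Shredder/detritivore
LECO-A63	Plecoptera	Pteronarcyidae	Pteronarcys	LECO	Shredder/detritivore
LECO-A64	Plecoptera	Perlidae	Acroneuria	LECO	Predators
LECO-A65	Plecoptera	Chloroperlidae	Alloperla	LECO	Predators
BIGC-A71	Diptera	Tipulidae	NA	BIGC	Predators
BIGC-A72	Odonata	Cordulegastridae	Cordulegaster	BIGC	Predators
BIGC-A73	Odonata	Gomphidae	NA	BIGC	Predators
BIGC-A74	Plecoptera	Chloroperlidae	Sweltsa	BIGC	Predators
BIGC-A75	Plecoptera	Leuctridae	NA	BIGC	Shredder/detritivore
MART-B1	Diptera	Tipulidae	Tipula	MART	Predators
MART-B2	Plecoptera	Chloroperlidae	Sweltsa	MART	Predators
MART-B3	Ephemeroptera	Ephemerellidae	Drunella	MART	Scrapers
MART-B4	Coleoptera	Elmidae	Narpus	MART	Gathering collectors
MART-B5	Coleoptera	Psephenidae	Ectopria	MART	Scrapers
POSE-B11	Coleoptera	Elmidae	Optioservus	POSE	Gathering collectors
POSE-B12	Ephemeroptera	Leptophlebiidae	Paraleptophlebia	POSE	Gathering collectors
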