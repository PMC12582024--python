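phrase	category
Agde	location
Alès	location
Avignon	location
Bordeaux	location
Béziers	location
Castelnau-le-Lez	location
Dijon	location
Frontignan	location
Gard	location
Grenoble	location
Hérault	location
Languedoc	location
Lattes	location
Lille	location
Lunel	location
Lyon	location
Marseille	location
Mauguio	location
Montpellier	location
Nantes	location
Nîmes	location
Occitanie	location
Paris	location
Perpignan	location
Rennes	location
Strasbourg	location
Sète	location
Toulouse	location
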