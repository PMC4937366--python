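taxon	marker	mz
Homininae	A	1235.6
Homininae	B	1477.8
Homininae	D	2115.1
Homininae	E	2832.4
Homininae	G	2957.5
Suidae	A	1240.5
Suidae	B	1453.8
Suidae	D	2105.7
Suidae	E	2840.2
Suidae	G	2962.8
Cervid	A	1180.4
Cervid	B	1427.6
Cervid	D	2131.3
Cervid	E	2792.5
Cervid	G	2883.4
Saiga	A	1180.4
Saiga	B	1427.6
Saiga	D	2131.3
Saiga	E	2792.5
Saiga	G	2883.4
Mustelidae	A	1196.3
Mustelidae	B	1453.2
Mustelidae	D	2099.9
Mustelidae	E	2808.7
Mustelidae	G	2901.6
Pantherinae	A	1214.7
Pantherinae	B	1453.2
Pantherinae	D	2099.9
Pantherinae	E	2808.7
Pantherinae	G	2901.6
Hyaenidae	A	1208.2
Hyaenidae	B	1453.2
Hyaenidae	D	2099.9
Hyaenidae	E	2808.7
Hyaenidae	G	2901.6
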