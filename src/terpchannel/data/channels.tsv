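# terpchannel default reaction-channel library (triterpenoid synthases)
# One record per carbocationic intermediate.
# columns: id	channel	index	rep	chemical_id	conformer_note	products
#   rep: representative rank used by hierarchical ranking (1 or 2), 0 otherwise
#   products: semicolon-separated name|EC entries ('-' if this cation is not a
#   product precursor in the default library)
# '!channel <id> disabled' marks a channel excluded from ranking by default.
!channel	D	disabled
A-I1	A	1	1	66-bicyclic-cation	chair-chair squalene fold	gamma-polypodatetraene|
A-I2	A	2	2	6665-tetracyclic-cation-A	all-chair 6,6,6,5-tetracycle	tetracyclic-abortive-products|
A-I3	A	3	0	secohopanyl-cation	ring-expansion cation en route to hopanyl	-
A-I4	A	4	0	hopanyl-cation	hopanyl cation, 6,6,6,6,5-pentacycle	hopene|5.4.99.17
B-I1	B	1	1	66-bicyclic-cation	chair-boat squalene fold	-
B-I2	B	2	2	dammarenyl-cation	dammarenyl-type 6,6,6,5-tetracycle	lupeol|5.4.99.41;dammara-20,24-diene|
C-I1	C	1	1	oxy-66-bicyclic-cation	chair-boat-chair oxidosqualene fold	-
C-I2	C	2	2	6665-tetracyclic-cation-C	6,6,6,5-tetracycle, protosteryl series	-
C-I3	C	3	0	protosteryl-precursor-1	hydride-shift series	-
C-I4	C	4	0	protosteryl-precursor-2	hydride-shift series	-
C-I5	C	5	0	protosteryl-cation	protosteryl cation	protosta-12,24-dien-3beta-ol|
C-I6	C	6	0	lanosteryl-precursor	C-8/C-9 cation region	lanosterol|5.4.99.7
C-I7	C	7	0	parkeol-precursor	methyl/hydride-shifted cation	parkeol|
C-I8	C	8	0	cycloartenol-precursor	C-9 cation, cyclopropane-forming	cycloartenol|5.4.99.8
C-I9	C	9	0	cucurbitadienol-precursor	further-shifted cation	cucurbitadienol|5.4.99.33
D-I1	D	1	1	c35-66-bicyclic-cation	sesquarterpene (C35) fold	-
D-I2	D	2	2	c35-tetracyclic-cation	sesquarterpene (C35) tetracycle	-
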