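gene_name	protein_name	ratio_hl	direction
AKAP12	A-kinase anchor protein 12	0.41	decreased
APOA1	Apolipoprotein A-I	0.07	decreased
APOC3	Apolipoprotein C-III variant 1	0.12	decreased
ARHGEF2	Rho guanine nucleotide exchange factor 2	0.52	decreased
CNBP	cDNA FLJ77718	0.42	decreased
CTRB1	cDNA FLJ77335, highly similar to Homo sapiens chymotrypsinogen B1 (CTRB1), mRNA	0.12	decreased
ERC1	ELKS/RAB6-interacting/CAST family member 1	0.63	decreased
FBLIM1	Filamin-binding LIM protein 1	0.62	decreased
FHL3	Four and a half LIM domains protein 3	0.59	decreased
HMGA2	HMGA2e	0.52	decreased
HPX	Hemopexin	0.22	decreased
ICAM1	Intercellular adhesion molecule 1	0.62	decreased
IGF2R	Cation-independent mannose-6-phosphate receptor	0.65	decreased
LTF	Lactotransferrin	0.05	decreased
MARCKSL1	MARCKS-related protein	0.58	decreased
MCAM	Cell surface glycoprotein MUC18	0.45	decreased
NES	NES protein	0.18	decreased
NUBP1	Nucleotide-binding protein 1	0.30	decreased
PCK2	cDNA FLJ50710, highly similar to Phosphoenolpyruvate carboxykinase (GTP), mitochondrial (EC 4.1.1.32)	0.57	decreased
PGPEP1	Pyroglutamyl-peptidase 1	0.65	decreased
POSTN	Periostin	0.25	decreased
PPIF	Peptidyl-prolyl cis-trans isomerase, mitochondrial	0.20	decreased
PZP	Pregnancy zone protein	0.11	decreased
SDCBP	Syndecan binding protein (Syntenin)	0.46	decreased
SLC2A1	Solute carrier family 2, facilitated glucose transporter member 1	0.52	decreased
SOLO	Protein SOLO	0.39	decreased
TAF15	TATA-binding protein-associated factor 2N	0.39	decreased
TNS1	Tensin-1	0.57	decreased
TRIP6	Thyroid receptor-interacting protein 6	0.64	decreased
AK6	Adenylate kinase isoenzyme 6	2.70	increased
AMIGO2	Amphoterin-induced protein 2	8.92	increased
ARSA	Arylsulfatase A	1.71	increased
CD9	CD9 antigen	2.48	increased
CNN3	Calponin-3	1.82	increased
COL8A1	Collagen alpha-1(VIII) chain	1.93	increased
CPA4	Carboxypeptidase A4	4.84	increased
CRYAB	Alpha-crystallin B chain	2.70	increased
CTSZ	Cathepsin Z	1.96	increased
DDAH1	N(G),N(G)-dimethylarginine dimethylaminohydrolase 1	2.50	increased
DNPEP	Aspartyl aminopeptidase	6.19	increased
DPP7	Dipeptidyl-peptidase 2	2.31	increased
GREM1	Gremlin-1	2.78	increased
LCRMP	Collapsin response mediator protein 4 long variant	4.38	increased
LPCAT2	Lysophosphatidylcholine acyltransferase 2	2.51	increased
MFI2	Melanotransferrin	2.91	increased
MYH10	Myosin-10	2.47	increased
NAAA	N-acylethanolamine-hydrolyzing acid amidase	2.83	increased
NAGLU	Alpha-N-acetylglucosaminidase	1.73	increased
P4HA1	Prolyl 4-hydroxylase subunit alpha-1	1.98	increased
PFKL	6-phosphofructokinase, liver type	1.98	increased
PLOD2	Procollagen-lysine,2-oxoglutarate 5-dioxygenase 2	7.77	increased
PPME1	Protein phosphatase methylesterase 1	1.82	increased
PYGL	Glycogen phosphorylase, liver form	1.81	increased
S100A10	Protein S100-A10	2.34	increased
SFXN1	Sideroflexin-1	1.71	increased
SIAE	Sialate O-acetylesterase	1.87	increased
SLC25A4	ADP/ATP translocase 1	2.24	increased
SOD1	Superoxide dismutase [Cu-Zn]	1.91	increased
TPM2	Tropomyosin beta chain	2.70	increased
UAP1	UDP-N-acetylhexosamine pyrophosphorylase	1.96	increased
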