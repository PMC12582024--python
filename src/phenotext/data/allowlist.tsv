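phrase	category
Angelman	medical_name
Beckwith-Wiedemann	medical_name
Coffin-Siris	medical_name
Cornelia de Lange	medical_name
DiGeorge	medical_name
Ehlers-Danlos	medical_name
Iso Kikuchi	medical_name
Kabuki	medical_name
Klinefelter	medical_name
Marfan	medical_name
Noonan	medical_name
Pierre Robin	medical_name
Prader-Willi	medical_name
Rett	medical_name
Silver-Russell	medical_name
Smith-Magenis	medical_name
Turner	medical_name
Williams	medical_name
amoxicillin	drug
baclofen	drug
carbamazepine	drug
clobazam	drug
ibuprofen	drug
lamotrigine	drug
levetiracetam	drug
melatonin	drug
omeprazole	drug
paracetamol	drug
risperidone	drug
topiramate	drug
valproate	drug
vigabatrin	drug
ANKRD11	gene
ARID1B	gene
CHD7	gene
DYRK1A	gene
FBN1	gene
KCNQ2	gene
KMT2D	gene
MECP2	gene
NSD1	gene
PTPN11	gene
SCN1A	gene
SHANK3	gene
STXBP1	gene
TCF4	gene
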