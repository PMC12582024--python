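abbreviation	expansion
BW	birth weight
CGH	comparative genomic hybridization
CSF	cerebrospinal fluid
CT	computed tomography
ECG	electrocardiogram
EEG	electroencephalogram
ENT	ear nose and throat
FTT	failure to thrive
GA	gestational age
GERD	gastroesophageal reflux disease
GI	gastrointestinal
IQ	intelligence quotient
MRI	magnetic resonance imaging
NICU	neonatal intensive care unit
OFC	occipitofrontal circumference
OT	occupational therapy
PT	physiotherapy
SLT	speech and language therapy
US	ultrasound
WES	whole exome sequencing
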