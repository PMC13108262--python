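name	description	format
organism	Scientific binomial name of the sampled organism.	free text
tissue	Anatomical tissue the sample derives from.	standard anatomy term
isolate	Identification of the specific individual sampled.	free text
age	Age of the organism at sampling.	non-negative integer, years
sex	Phenotypic sex of the sampled organism.	male | female
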