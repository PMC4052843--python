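-- ICD-10 subset for the acute-stroke content (reconstructed, non-normative
-- except I64 and G83.8).  Code nesting (G83.8 under G83) is encoded as
-- explicit parent links, not string-prefix logic.
code	display	parents
I64	Stroke, not specified as haemorrhage or infarction
I61	Intracerebral haemorrhage
I62	Other nontraumatic intracranial haemorrhage
G83	Other paralytic syndromes
G83.8	Other specified paralytic syndromes	G83
R57	Shock, not elsewhere classified
R57.2	Septic shock	R57
D68	Other coagulation defects
I33	Acute and subacute endocarditis
I30	Acute pericarditis
I50	Heart failure
K85	Acute pancreatitis
K72	Hepatic failure, not elsewhere classified
S06	Intracranial injury
K92	Other diseases of digestive system
K92.2	Gastrointestinal haemorrhage, unspecified	K92
K26	Duodenal ulcer
R31	Unspecified haematuria
Z33	Pregnant state, incidental
O80	Single spontaneous delivery
Z39	Postpartum care and examination
Z39.1	Care and examination of lactating mother	Z39
R51	Headache
I10	Essential hypertension
G43	Migraine
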