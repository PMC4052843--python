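-- SNOMED CT subset for the acute-stroke content (reconstructed, non-normative).
-- Only a handful of concept identifiers are normative for this content
-- (230690007, 66264000, 50960005, 12738006); the remainder are curated
-- placeholders sufficient for subsumption queries over this rule set.
code	display	parents
404684003	Clinical finding
123037004	Body structure
71388002	Procedure
105590001	Substance
230690007	Cerebrovascular accident	404684003
422504002	Ischaemic stroke	230690007
429993008	Posterior circulation stroke syndrome	230690007
274100004	Cerebral haemorrhage	404684003
1386000	Intracranial haemorrhage	404684003
95660002	Thunderclap headache	404684003
66264000	Postictal paralysis	404684003
76571007	Septic shock	404684003
64779008	Blood coagulation disorder	404684003
56819008	Infective endocarditis	404684003
3238004	Pericarditis	404684003
91434003	Ventricular thrombosis	404684003
253276004	Atrial septal aneurysm	404684003
84114007	Heart failure	404684003
75694006	Pancreatitis	404684003
235856003	Severe liver damage	404684003
82271004	Head injury	404684003
74474003	Gastrointestinal haemorrhage	404684003
51868009	Duodenal ulcer	404684003
53298000	Bleeding from urinary tract	404684003
283545005	Trauma with internal injury	404684003
77386006	Pregnancy	404684003
169750002	Breastfeeding	404684003
386216000	Recent childbirth	404684003
38341003	Hypertensive disorder	404684003
37796009	Migraine	404684003
50582007	Hemiplegia	404684003
371040005	No abnormality on CT of brain	404684003
373930000	Stroke mimic suspected	404684003
17621005	Normal examination finding	404684003
50960005	Haemorrhage	404684003
12738006	Brain structure	123037004
91602002	Lumbar puncture	71388002
392247006	Insertion of central venous catheter	71388002
86273004	Biopsy of parenchymatous organ	71388002
107963000	Surgical operation on parenchymatous organ	71388002
118831003	Operation on central nervous system	71388002
426347000	Thrombolysis therapy	71388002
29303009	Electrocardiogram	71388002
16310003	Ultrasound scan	71388002
24099007	Oxygen gas	105590001
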