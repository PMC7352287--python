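# Toy PT -> HLT -> HLGT -> SOC mapping for tests and demos.
# The licensed MedDRA dictionary cannot ship with the package; supply a
# real mapping in this same four-column format for production use.
pt	hlt	hlgt	soc
rash	rashes eruptions and exanthems nec	epidermal and dermal conditions	skin and subcutaneous tissue disorders
rash generalised	rashes eruptions and exanthems nec	epidermal and dermal conditions	skin and subcutaneous tissue disorders
rash maculo-papular	rashes eruptions and exanthems nec	epidermal and dermal conditions	skin and subcutaneous tissue disorders
drug reaction with eosinophilia and systemic symptoms	rashes eruptions and exanthems nec	epidermal and dermal conditions	skin and subcutaneous tissue disorders
erythema multiforme	erythemas	epidermal and dermal conditions	skin and subcutaneous tissue disorders
stevens-johnson syndrome	bullous conditions	epidermal and dermal conditions	skin and subcutaneous tissue disorders
toxic epidermal necrolysis	bullous conditions	epidermal and dermal conditions	skin and subcutaneous tissue disorders
photosensitivity reaction	photosensitivity and photodermatosis conditions	epidermal and dermal conditions	skin and subcutaneous tissue disorders
pruritus	pruritus nec	epidermal and dermal conditions	skin and subcutaneous tissue disorders
pyrexia	febrile disorders	body temperature conditions	general disorders and administration site conditions
chills	febrile disorders	body temperature conditions	general disorders and administration site conditions
hyperthermia	temperature regulation disorders	body temperature conditions	general disorders and administration site conditions
fatigue	asthenic conditions	general system disorders nec	general disorders and administration site conditions
asthenia	asthenic conditions	general system disorders nec	general disorders and administration site conditions
malaise	feelings and sensations nec	general system disorders nec	general disorders and administration site conditions
death	death and sudden death	fatal outcomes	general disorders and administration site conditions
sudden death	death and sudden death	fatal outcomes	general disorders and administration site conditions
c-reactive protein increased	acute phase proteins	biochemical investigations	investigations
blood creatinine increased	renal function analyses	renal and urinary tract investigations	investigations
renal disorder	renal disorders nec	renal disorders (excl nephropathies)	renal and urinary disorders
renal impairment	renal failure and impairment	renal disorders (excl nephropathies)	renal and urinary disorders
renal failure	renal failure and impairment	renal disorders (excl nephropathies)	renal and urinary disorders
acute kidney injury	renal failure and impairment	renal disorders (excl nephropathies)	renal and urinary disorders
colitis	colitis (excl infective)	gastrointestinal inflammatory conditions	gastrointestinal disorders
diarrhoea	diarrhoea (excl infective)	gastrointestinal motility and defaecation conditions	gastrointestinal disorders
constipation	gastrointestinal atonic and hypomotility conditions nec	gastrointestinal motility and defaecation conditions	gastrointestinal disorders
nausea	nausea and vomiting symptoms	gastrointestinal signs and symptoms	gastrointestinal disorders
vomiting	nausea and vomiting symptoms	gastrointestinal signs and symptoms	gastrointestinal disorders
abdominal pain upper	gastrointestinal and abdominal pains (excl oral and throat)	gastrointestinal signs and symptoms	gastrointestinal disorders
seizure	seizures and seizure disorders nec	seizures (incl subtypes)	nervous system disorders
status epilepticus	seizures and seizure disorders nec	seizures (incl subtypes)	nervous system disorders
guillain-barre syndrome	acute polyneuropathies	peripheral neuropathies	nervous system disorders
neuropathy peripheral	peripheral neuropathies nec	peripheral neuropathies	nervous system disorders
peripheral sensory neuropathy	peripheral neuropathies nec	peripheral neuropathies	nervous system disorders
peripheral motor neuropathy	peripheral neuropathies nec	peripheral neuropathies	nervous system disorders
facial paralysis	facial cranial nerve disorders	cranial nerve disorders (excl neoplasms)	nervous system disorders
hypotension	vascular hypotensive disorders	decreased and nonspecific blood pressure disorders and shock	vascular disorders
circulatory collapse	vascular hypotensive disorders	decreased and nonspecific blood pressure disorders and shock	vascular disorders
malignant neoplasm progression	oncologic complications and emergencies	neoplasm related morbidities	neoplasms benign malignant and unspecified (incl cysts and polyps)
squamous cell carcinoma of skin	skin neoplasms malignant and unspecified	skin neoplasms malignant and unspecified	neoplasms benign malignant and unspecified (incl cysts and polyps)
off-label use	product use issues nec	medication errors and other product use errors and issues	injury poisoning and procedural complications
product use issue	product use issues nec	medication errors and other product use errors and issues	injury poisoning and procedural complications
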