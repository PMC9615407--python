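token	category	action
statin	cardiovascular_disease	include
ace_inhibitor	cardiovascular_disease	include
beta_blocker	cardiovascular_disease	include
loop_diuretic	cardiovascular_disease	include
opioid_analgesic	chronic_pain	include
gabapentinoid	chronic_pain	include
nsaid	arthritis	include
intra_articular_steroid	arthritis	include
ssri	affective_disorders	include
snri	affective_disorders	include
mirtazapine	affective_disorders	include
tricyclic_antidepressant	affective_disorders	exclude
proton_pump_inhibitor	acid_related_disorders	include
h2_antagonist	acid_related_disorders	include
inhaled_bronchodilator	asthma_copd	include
inhaled_corticosteroid	asthma_copd	include
leukotriene_antagonist	asthma_copd	include
metformin	diabetes_mellitus	include
insulin	diabetes_mellitus	include
sulfonylurea	diabetes_mellitus	include
bisphosphonate	osteoporosis	include
denosumab	osteoporosis	include
levothyroxine	thyroid_disease	include
antithyroid_agent	thyroid_disease	include
oral_anticoagulant	thromboembolic_disease	include
low_molecular_weight_heparin	thromboembolic_disease	include
conventional_dmard	inflammatory_conditions	include
biologic_dmard	inflammatory_conditions	include
systemic_corticosteroid	inflammatory_conditions	exclude
alpha_blocker_urological	benign_prostatic_hyperplasia	include
five_alpha_reductase_inhibitor	benign_prostatic_hyperplasia	include
allopurinol	gout	include
colchicine	gout	include
ocular_prostaglandin	glaucoma	include
ocular_beta_blocker	glaucoma	include
urinary_antimuscarinic	urinary_incontinence	include
mirabegron	urinary_incontinence	include
pde5_inhibitor	erectile_dysfunction	include
antipsychotic	psychotic_disorders	include
lithium	psychotic_disorders	include
antiepileptic	epilepsy	include
triptan	migraine	include
migraine_prophylactic	migraine	include
levodopa	parkinsonism	include
dopamine_agonist	parkinsonism	include
cholinesterase_inhibitor	dementia	include
memantine	dementia	include
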