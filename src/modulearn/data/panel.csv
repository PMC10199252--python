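variable_id,questionnaire,subscale_name,is_total_score,improvement_direction
adhd_total,ADHD-SR,ADHD symptoms total,True,1
adhd_attention_problems,ADHD-SR,Attention problems,False,1
adhd_impulsivity,ADHD-SR,Impulsivity,False,1
adhd_hyperactivity,ADHD-SR,Hyperactivity,False,1
npi_total,NPI-40,Narcissistic personality total,True,1
npi_self_sufficiency,NPI-40,Self-sufficiency,False,1
npi_authority,NPI-40,Authority,False,1
npi_exhibitionism,NPI-40,Exhibitionism,False,1
npi_exploitativeness,NPI-40,Exploitativeness,False,1
npi_vanity,NPI-40,Vanity,False,1
npi_entitlement,NPI-40,Entitlement,False,1
npi_superiority,NPI-40,Superiority,False,1
bpq_total,BPQ,Borderline features total,True,1
bpq_emotional_reactivity,BPQ,Emotional reactivity / affective instability,False,1
bpq_abandonment_fear,BPQ,Fear of abandonment,False,1
bpq_self_image_instability,BPQ,Unstable self-image,False,1
bpq_impulsiveness,BPQ,Impulsiveness,False,1
bpq_emptiness,BPQ,Chronic emptiness,False,1
bpq_intense_anger,BPQ,Intense anger,False,1
bpq_quasi_psychotic,BPQ,Quasi-psychotic states,False,1
bpq_relationship_instability,BPQ,Unstable relationships,False,1
bpq_self_harm,BPQ,Self-harm,False,1
mach_total,MACH,Machiavellism total,True,1
mhc_total,MHC-SF,Mental health continuum total,True,-1
mhc_emotional_wellbeing,MHC-SF,Emotional wellbeing,False,-1
mhc_social_wellbeing,MHC-SF,Social wellbeing,False,-1
mhc_psychological_wellbeing,MHC-SF,Psychological wellbeing,False,-1
pcs_total,PCS,Pain catastrophizing total,True,1
pcs_rumination,PCS,Pain rumination,False,1
pcs_magnification,PCS,Pain magnification,False,1
pcs_helplessness,PCS,Pain helplessness,False,1
swls_life_satisfaction,SWLS,Satisfaction with life,True,-1
ius_total,IUS,Intolerance of uncertainty total,True,1
ius_negative_affect_uncertainty,IUS,Negative affect by uncertainty,False,1
ius_uncertainty_paralysis,IUS,Uncertainty paralyses action,False,1
bdi_total,BDI-II,Depressive symptoms total,True,1
bdi_cognitive_affective,BDI-II,Cognitive-affective symptoms,False,1
bdi_somatic,BDI-II,Somatic symptoms,False,1
tics_screening,TICS,Chronic stress screening scale,True,1
tics_work_overload,TICS,Stress by work demands (work overload),False,1
tics_social_overload,TICS,Stress by social overload,False,1
tics_social_recognition_lack,TICS,Stress by lack of social recognition,False,1
tics_pressure_to_perform,TICS,Pressure to perform,False,1
tics_work_discontent,TICS,Work discontent,False,1
tics_excessive_demands,TICS,Excessive demands at work,False,1
tics_social_tension,TICS,Social tensions,False,1
tics_social_isolation,TICS,Social isolation,False,1
tics_chronic_worry,TICS,Chronic worrying,False,1
ucla_loneliness,UCLA,Loneliness,True,1
pss_perceived_stress,PSS,Perceived stress,True,1
psqi_total,PSQI,Sleep quality total,True,1
psqi_sleep_quality,PSQI,Subjective sleep quality,False,1
psqi_sleep_latency,PSQI,Sleep latency,False,1
psqi_sleep_duration,PSQI,Sleep duration,False,1
psqi_sleep_disturbance,PSQI,Sleep disturbances,False,1
psqi_daytime_dysfunction,PSQI,Daytime dysfunction,False,1
fbl_total,FBL,Bodily complaints total,True,1
fbl_tiredness,FBL,Tiredness,False,1
fbl_sensory_problems,FBL,Sensory problems,False,1
fbl_cardiovascular_problems,FBL,Cardiovascular problems,False,1
fbl_gastrointestinal_problems,FBL,Gastrointestinal problems,False,1
fbl_musculoskeletal_pain,FBL,Musculoskeletal pain,False,1
fbl_general_complaints,FBL,General complaints,False,1
tas_total,TAS-20,Alexithymia total,True,1
tas_identify_feelings,TAS-20,Difficulty identifying feelings,False,1
tas_describe_feelings,TAS-20,Difficulty describing feelings,False,1
tas_external_thinking,TAS-20,Externally oriented thinking,False,1
stai_trait_anxiety,STAI,Trait anxiety,True,1
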