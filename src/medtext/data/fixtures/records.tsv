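subject_id	medication_raw	reason_raw
S0001	Fexafenedine	allergies
S0001	fexfenadine	allergies
S0002	Hydrochlorothazide	high blood pressure
S0002	Hydrochlorthiazide	HTN
S0003	Metoprolol Succ ER	high blood pressure
S0003	Metoprolol Tart	b/p
S0004	Quinipril	hypertension
S0005	Vit B12	
S0005	vitemin B12	
S0006	aspirin	headache
S0007	ibuprofen 200 mg	arthritis
S0008	Albuteral Inhaler	asthmatic
S0009	Metoprold ER	high blood pressure
S0010	xanthozep	ulcerative colitis
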