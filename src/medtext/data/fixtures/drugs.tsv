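canonical_name	synonyms	concept_id	atc_codes
fexofenadine	allegra	RXSYN00001	R06A:antihistamines
hydrochlorothiazide	hctz|microzide	RXSYN00002	C03A:diuretics
metoprolol	lopressor|toprol	RXSYN00003	C07A:beta-adrenergic blocking agents
quinapril	accupril	RXSYN00004	C09A:angiotensin converting enzyme inhibitors
aspirin	asa|bayer aspirin	RXSYN00005	N02B:analgesics and antipyretics|B01A:antithrombotic agents
albuterol	proventil|ventolin	RXSYN00006	R03A:adrenergics, inhalants
ibuprofen	advil|motrin	RXSYN00007	M01A:antiinflammatory and antirheumatic products, non-steroids
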