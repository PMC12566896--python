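# 52 thrombosis-related MedDRA preferred terms (narrow SMQ scope).
# Scope labels (arterial/venous/mixed) are this package's curated SMQ-based
# assignment — the source term list does not print scopes; override freely.
pt	scope
ACUTE CORONARY SYNDROME	arterial
ACUTE MYOCARDIAL INFARCTION	arterial
ARTERIAL OCCLUSIVE DISEASE	arterial
BLINDNESS TRANSIENT	arterial
CARDIAC VENTRICULAR THROMBOSIS	mixed
CAROTID ARTERY OCCLUSION	arterial
CENTRAL VENOUS CATHETERISATION	venous
CEREBRAL INFARCTION	arterial
CEREBRAL ISCHAEMIA	arterial
CEREBRAL THROMBOSIS	arterial
CEREBROVASCULAR ACCIDENT	arterial
CEREBROVASCULAR DISORDER	arterial
CORONARY ARTERIAL STENT INSERTION	arterial
CORONARY ARTERY BYPASS	arterial
CORONARY ARTERY OCCLUSION	arterial
DEEP VEIN THROMBOSIS	venous
DEVICE OCCLUSION	mixed
DISSEMINATED INTRAVASCULAR COAGULATION	mixed
EMBOLIC STROKE	arterial
EMBOLISM	mixed
EMBOLISM VENOUS	venous
HAEMORRHAGIC STROKE	arterial
HEMIPARESIS	arterial
HEMIPLEGIA	arterial
HEPARIN-INDUCED THROMBOCYTOPENIA	mixed
INFARCTION	mixed
ISCHAEMIC STROKE	arterial
LACUNAR INFARCTION	arterial
MONOPLEGIA	arterial
MYOCARDIAL INFARCTION	arterial
PARAPLEGIA	arterial
PARESIS	arterial
PERIPHERAL ARTERIAL OCCLUSIVE DISEASE	arterial
PORTAL VEIN THROMBOSIS	venous
PULMONARY EMBOLISM	venous
PULMONARY INFARCTION	venous
PULMONARY THROMBOSIS	venous
RETINAL ARTERY OCCLUSION	arterial
RETINAL VEIN OCCLUSION	venous
STRESS CARDIOMYOPATHY	arterial
SUPERFICIAL VEIN THROMBOSIS	venous
THROMBOPHLEBITIS	venous
THROMBOSIS	mixed
THROMBOSIS IN DEVICE	mixed
THROMBOTIC MICROANGIOPATHY	mixed
THROMBOTIC THROMBOCYTOPENIC PURPURA	mixed
TRANSIENT ISCHAEMIC ATTACK	arterial
VASCULAR GRAFT	mixed
VENOOCCLUSIVE DISEASE	venous
VENOOCCLUSIVE LIVER DISEASE	venous
VENOUS THROMBOSIS	venous
VENOUS THROMBOSIS LIMB	venous
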