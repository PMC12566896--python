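# Non-structural steroid names force-included in the cohort: reporting
# database entries without a single resolvable structure (class names,
# combination labels, botanical extracts).
drug_name
STEROIDS
EMERGENCY CONTRACEPTIVES
WITHANIA SOMNIFERA
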