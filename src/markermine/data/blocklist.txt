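# Very general terms removed from the dictionaries during curation.
# Normalized forms, one per line; user-editable.
disease
diseases
syndrome
syndromes
disorder
disorders
condition
conditions
abnormality
abnormalities
deficiency
finding
findings
symptom
symptoms
lesion
lesions
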