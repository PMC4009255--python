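# Biomarker trigger terms, seeded from the MeSH "Biological Markers"
# concept entry terms plus the common singular/plural surface forms.
# One term per line; user-editable.
biomarker
biomarkers
biological marker
biological markers
biologic marker
biologic markers
marker
markers
surrogate marker
surrogate markers
surrogate endpoint
surrogate endpoints
clinical marker
clinical markers
laboratory marker
laboratory markers
serum marker
serum markers
plasma marker
plasma markers
immunologic marker
immunologic markers
immune marker
immune markers
viral marker
viral markers
biochemical marker
biochemical markers
prognostic marker
prognostic markers
diagnostic marker
diagnostic markers
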