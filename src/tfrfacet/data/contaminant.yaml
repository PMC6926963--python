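# Cadmium screening configuration: concentration in the food (mg/kg) and
# the US EPA chronic oral reference dose (mg/kg-bw/day).
name: cadmium
concentration_mg_per_kg: 0.04
rfd_mg_per_kg_day: 0.001
provenance: "US EPA IRIS, CASRN 7440-43-9"
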