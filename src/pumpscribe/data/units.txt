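# Dose-rate unit strings as shown on the display, one per line, lowercase.
ml/hr
mg/hr
mcg/hr
mcg/kg/min
mcg/min
mg/kg/hr
mg/min
units/hr
units/kg/hr
ml
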