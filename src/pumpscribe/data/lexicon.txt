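# Medication names and display vocabulary recognized on the pump screen.
# One lowercase alphabetic word per line; '#' starts a comment.
fentanyl
propofol
sodium
chloride
saline
heparin
insulin
midazolam
morphine
norepinephrine
epinephrine
dopamine
dobutamine
vasopressin
ketamine
dexmedetomidine
phenylephrine
nitroglycerin
furosemide
amiodarone
mannitol
rocuronium
cisatracurium
dextrose
levetiracetam
# display vocabulary (non-drug words that can appear as keywords)
infusing
remaining
volume
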