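# Indirect-calorimetry substrate oxidation coefficients (g/min from L/min):
#   fat = a1*VO2 - a2*VCO2 ; cho = b1*VCO2 - b2*VO2
# rest: Frayn whole-body equations; exercise: moderate-to-high-intensity
# coefficients. Editable; both sets assume negligible protein oxidation.
# context	a1	a2	b1	b2
rest	1.67	1.67	4.55	3.21
exercise	1.695	1.701	4.210	2.962
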