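target,kidneys,salivary_glands,liver,spleen,remainder_of_body
kidneys,0.275182,1.0e-05,2.0e-04,2.0e-04,1.5e-04
salivary_glands,1.0e-05,1.003604,1.0e-05,1.0e-05,1.5e-04
liver,2.0e-04,1.0e-05,0.0473924,2.0e-04,1.5e-04
spleen,2.0e-04,1.0e-05,2.0e-04,0.568709,1.5e-04
whole_body,1.36e-03,1.36e-03,1.36e-03,1.36e-03,1.36e-03
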