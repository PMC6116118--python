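sex,age_year,waist_p90
girl,8,66.0
girl,9,69.0
girl,10,72.0
girl,11,75.0
girl,12,78.0
boy,8,68.0
boy,9,71.0
boy,10,74.0
boy,11,77.0
boy,12,80.0
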