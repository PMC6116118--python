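sex,age_year,component,mean,sd
girl,8,triglycerides,75.0,28.0
girl,8,hdl,55.0,11.0
girl,8,glucose,84.5,6.0
girl,8,sbp,99.0,9.0
girl,8,dbp,60.0,7.0
girl,9,triglycerides,76.0,28.0
girl,9,hdl,54.6,11.0
girl,9,glucose,84.8,6.0
girl,9,sbp,100.6,9.0
girl,9,dbp,60.8,7.0
girl,10,triglycerides,77.0,28.0
girl,10,hdl,54.2,11.0
girl,10,glucose,85.1,6.0
girl,10,sbp,102.2,9.0
girl,10,dbp,61.6,7.0
girl,11,triglycerides,78.0,28.0
girl,11,hdl,53.8,11.0
girl,11,glucose,85.4,6.0
girl,11,sbp,103.8,9.0
girl,11,dbp,62.4,7.0
girl,12,triglycerides,79.0,28.0
girl,12,hdl,53.4,11.0
girl,12,glucose,85.7,6.0
girl,12,sbp,105.4,9.0
girl,12,dbp,63.2,7.0
boy,8,triglycerides,72.0,28.0
boy,8,hdl,56.0,11.0
boy,8,glucose,85.5,6.0
boy,8,sbp,99.5,9.0
boy,8,dbp,60.0,7.0
boy,9,triglycerides,73.0,28.0
boy,9,hdl,55.6,11.0
boy,9,glucose,85.8,6.0
boy,9,sbp,101.1,9.0
boy,9,dbp,60.8,7.0
boy,10,triglycerides,74.0,28.0
boy,10,hdl,55.2,11.0
boy,10,glucose,86.1,6.0
boy,10,sbp,102.7,9.0
boy,10,dbp,61.6,7.0
boy,11,triglycerides,75.0,28.0
boy,11,hdl,54.8,11.0
boy,11,glucose,86.4,6.0
boy,11,sbp,104.3,9.0
boy,11,dbp,62.4,7.0
boy,12,triglycerides,76.0,28.0
boy,12,hdl,54.4,11.0
boy,12,glucose,86.7,6.0
boy,12,sbp,105.9,9.0
boy,12,dbp,63.2,7.0
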