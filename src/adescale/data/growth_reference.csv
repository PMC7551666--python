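maturity,age_years,median_weight_kg
preterm,0.0,1.2
preterm,0.0833,1.8
preterm,0.1667,2.4
preterm,0.25,3.0
term,0.0,3.4
term,0.0833,4.4
term,0.25,6.0
term,0.5,7.5
term,0.75,8.6
term,1.0,9.5
term,1.5,10.9
term,2.0,12.2
term,3.0,14.2
term,4.0,16.3
term,5.0,18.3
term,6.0,20.5
term,7.0,23.0
term,8.0,25.8
term,9.0,28.8
term,10.0,32.0
term,11.0,36.0
term,12.0,40.5
term,13.0,45.5
term,14.0,50.5
term,15.0,55.5
term,16.0,60.0
term,17.0,64.5
term,18.0,70.0
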