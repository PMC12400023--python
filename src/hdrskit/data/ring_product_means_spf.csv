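# Published product-specific mean SPF values from the LED-HDRS ring trial
# re-evaluation: reference method (in vivo erythema) vs alternative method.
product_code,mean_ref,mean_alt
PG1_1,29.3,33.0
PG1_2,43.3,42.4
PG1_3,39.4,32.2
PG1_4,52.7,45.1
PG2_3,6.4,8.5
PG3_3,18.7,20.1
S2,16.8,24.8
PG4_2,26.3,29.3
P5,30.6,34.9
P6,43.0,67.1
P8,63.1,88.2
PG8_2,60.1,53.3
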