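# Published product-specific mean UVA-PF values from the LED-HDRS ring
# trial re-evaluation: reference in vitro method vs alternative method.
# P6 has no reference value and is omitted.
product_code,mean_ref,mean_alt
PG1_1,14.6,12.9
PG1_2,19.9,15.8
PG1_3,9.1,9.4
PG1_4,17.8,18.5
PG2_3,2.9,4.2
PG3_3,8.9,10.1
S2,12.7,17.1
PG4_2,11.3,15.2
P5,13.4,14.3
P8,27.5,33.0
PG8_2,16.7,15.8
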