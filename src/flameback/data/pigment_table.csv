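name,n_keto_c4,n_oxy_c3,n_epsilon_rings,origin_class
lutein,0,2,1,dietary_yellow
zeaxanthin,0,2,0,dietary_yellow
beta-cryptoxanthin,0,1,0,dietary_yellow
beta-carotene,0,0,0,dietary_yellow
3'-dehydro-lutein,0,2,1,metabolised_yellow
canary-xanthophyll A,0,2,2,metabolised_yellow
canary-xanthophyll B,0,2,2,metabolised_yellow
canthaxanthin,2,0,0,metabolised_red
adonirubin,2,1,0,metabolised_red
astaxanthin,2,2,0,metabolised_red
alpha-doradexanthin,1,2,1,metabolised_red
papilioerythrinone,1,2,1,metabolised_red
adonixanthin,1,2,0,metabolised_red
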