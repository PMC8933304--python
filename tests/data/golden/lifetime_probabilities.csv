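# config_hash=2de40eb911b254e9
# seed=0
sex,outcome,from_age,probability,percent
male,hip,50,0.09727335003,9.7
male,mof,50,0.176852482,17.7
female,hip,50,0.1127468515,11.3
female,mof,50,0.2826581115,28.3
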