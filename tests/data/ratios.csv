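# synthetic illustrative other-MOF:hip ratios for tests; not the Swedish values
sex,age_band,ratio
female,40-44,6
female,45-49,5.5
female,50-54,5
female,55-59,4.5
female,60-64,3.8
female,65-69,3
female,70-74,2.4
female,75-79,1.9
female,80+,1.5
male,40-44,4
male,45-49,3.5
male,50-54,3
male,55-59,2.5
male,60-64,2
male,65-69,1.6
male,70-74,1.2
male,75-79,1
male,80+,0.8
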