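# config_hash=2de40eb911b254e9
# seed=0
age,horizon,probability,percent,sex,outcome
50,10,0.00318594072,0.318594072,male,hip
55,10,0.005209883562,0.5209883562,male,hip
60,10,0.008737471545,0.8737471545,male,hip
65,10,0.01493832283,1.493832283,male,hip
70,10,0.02579152699,2.579152699,male,hip
75,10,0.04431714662,4.431714662,male,hip
80,10,0.0741532695,7.41532695,male,hip
85,10,0.104294268,10.4294268,male,hip
90,10,0.1081521832,10.81521832,male,hip
50,10,0.01171722941,1.171722941,male,mof
55,10,0.01653054796,1.653054796,male,mof
60,10,0.02385639863,2.385639863,male,mof
65,10,0.03476631431,3.476631431,male,mof
70,10,0.05275408217,5.275408217,male,mof
75,10,0.0814175888,8.14175888,male,mof
80,10,0.1282699972,12.82699972,male,mof
85,10,0.1767315709,17.67315709,male,mof
90,10,0.1827538749,18.27538749,male,mof
50,10,0.004535178485,0.4535178485,female,hip
55,10,0.007917852454,0.7917852454,female,hip
60,10,0.01349798628,1.349798628,female,hip
65,10,0.02234462011,2.234462011,female,hip
70,10,0.03561821689,3.561821689,female,hip
75,10,0.0540086591,5.40086591,female,hip
80,10,0.07663091326,7.663091326,female,hip
85,10,0.09326317313,9.326317313,female,hip
90,10,0.08885208399,8.885208399,female,hip
50,10,0.02549257008,2.549257008,female,mof
55,10,0.03940563072,3.940563072,female,mof
60,10,0.05675735685,5.675735685,female,mof
65,10,0.07871308244,7.871308244,female,mof
70,10,0.1060951444,10.60951444,female,mof
75,10,0.1370177251,13.70177251,female,mof
80,10,0.1779933366,17.79933366,female,mof
85,10,0.2117448725,21.17448725,female,mof
90,10,0.2019270241,20.19270241,female,mof
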