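# config_hash=2de40eb911b254e9
# seed=0
sex,nationality,rate,ci_low,ci_high,se,p_vs_other
male,national,80.73817762,56.23709897,112.2872604,13.64724287,0.04576285511
male,expatriate,125.4575163,93.03279911,166.7925287,17.7924184,0.04576285511
female,national,103.8062284,75.71697529,138.9009008,15.47451888,0.2792787282
female,expatriate,129.7846982,96.02673561,172.656982,18.53394313,0.2792787282
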