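# synthetic fixture: generated by fraxkit.synthetic, seed=4242, half-size default populations
sex,age,m,q
male,40,0.002063929378,0.00206180094
male,41,0.002201793878,0.002199371708
male,42,0.002352641669,0.002349876377
male,43,0.002517695443,0.002514528706
male,44,0.002698293038,0.002694655917
male,45,0.002895898282,0.002891709213
male,46,0.003112112858,0.003107275254
male,47,0.003348689287,0.00334308868
male,48,0.003607545132,0.003601045759
male,49,0.00389077854,0.003883219268
male,50,0.004200685252,0.004191874715
male,51,0.004539777206,0.004529487994
male,52,0.004910802903,0.004898764624
male,53,0.005316769678,0.005302660674
male,54,0.005760968084,0.005744405528
male,55,0.006246998557,0.00622752663
male,56,0.006778800601,0.006755876361
male,57,0.007360684722,0.007333661226
male,58,0.007997367363,0.007965473499
male,59,0.008694009136,0.008656325524
male,60,0.009456256648,0.009411686852
male,61,0.01029028827,0.0102375244
male,62,0.01120286423,0.01114034583
male,63,0.01220138138,0.01212724634
male,64,0.01329393316,0.0132059591
male,65,0.01448937522,0.01438490938
male,66,0.01579739718,0.01567327278
male,67,0.01722860118,0.01708103748
male,68,0.01879458778,0.01861907082
male,69,0.02050805005,0.0202991902
male,70,0.02238287641,0.02213423836
male,71,0.02443426319,0.02413816314
male,72,0.02667883785,0.02632610148
male,73,0.02913479373,0.02871446755
male,74,0.03182203749,0.03132104472
male,75,0.0347623505,0.03416508083
male,76,0.03797956539,0.03726738624
male,77,0.04149975918,0.04065043363
male,78,0.04535146471,0.04433845851
male,79,0.04956590184,0.04835755892
male,80,0.05417723058,0.05273579256
male,81,0.05922282789,0.0575032688
male,82,0.06474359071,0.06269223302
male,83,0.07078426742,0.06833713952
male,84,0.07739382053,0.07447470904
male,85,0.08462582358,0.08114396565
male,86,0.09253889532,0.08838624724
male,87,0.1011971749,0.09624518248
male,88,0.1106708418,0.1047666262
male,89,0.1210366845,0.1139985435
male,90,0.132378723,0.1239908326
male,91,0.1447888899,0.1347950726
male,92,0.1583677753,0.1464641851
male,93,0.1732254425,0.159051992
male,94,0.1894823199,0.1726126549
male,95,0.2072701771,0.1871999796
male,96,0.226733193,0.2028665653
male,97,0.2480291244,0.2196627839
male,98,0.271330585,0.2376355715
male,99,0.2968264439,0.2568270166
male,100,0.3247233571,0.2772727366
male,101,0.3552474421,0.2990000352
male,102,0.3886461109,0.3220258448
male,103,0.4251900755,0.3463544687
male,104,0.4651755417,0.371975149
male,105,0.5089266105,0.3988595095
female,40,0.001517529612,0.001516378747
female,41,0.001628901334,0.001627575394
female,42,0.001751372234,0.001749839477
female,43,0.001886048444,0.001884270972
female,44,0.00203414633,0.002032078857
female,45,0.002197003483,0.002194591837
female,46,0.002376090792,0.002373270123
female,47,0.002573025738,0.002569718345
female,48,0.002789586996,0.002785699713
female,49,0.0030277305,0.003023151546
female,50,0.003289607113,0.003284202284
female,51,0.00357758205,0.003571190128
female,52,0.003894256239,0.003886683456
female,53,0.004242489815,0.004233503168
female,54,0.004625427951,0.004614747133
female,55,0.005046529263,0.005033816928
female,56,0.00550959705,0.005494447056
female,57,0.006018813642,0.006000736868
female,58,0.006578778177,0.006557185393
female,59,0.007194548136,0.00716872933
female,60,0.007871685024,0.007840784445
female,61,0.0086163046,0.008579290631
female,62,0.009435132109,0.009390760909
female,63,0.01033556303,0.01028233464
female,64,0.01132572987,0.01126183523
female,65,0.0124145756,0.01233783266
female,66,0.01361193445,0.01351971099
female,67,0.01492862071,0.01481774129
female,68,0.01637652641,0.01624316012
female,69,0.01796872875,0.01780825375
female,70,0.01971960814,0.01952644843
female,71,0.02164497817,0.02141240665
female,72,0.02376222837,0.0234821296
female,73,0.0260904813,0.02575306551
female,74,0.02865076525,0.02824422391
female,75,0.03146620418,0.03097629515
female,76,0.03456222652,0.03397177476
female,77,0.0379667949,0.0372550916
female,78,0.04171065867,0.04085273863
female,79,0.04582763162,0.04479340458
female,80,0.05035489738,0.04910810443
female,81,0.05533334526,0.0538303058
female,82,0.06080793955,0.05899604794
female,83,0.06682812565,0.06464404878
female,84,0.0734482766,0.07081579489
female,85,0.08072818422,0.07755560768
female,86,0.08873359909,0.08491067827
female,87,0.09753682445,0.09293106137
female,88,0.1072173692,0.1016696176
female,89,0.1178626659,0.1111818907
female,90,0.1295688607,0.121525906
female,91,0.1424416815,0.1327618711
female,92,0.1565973928,0.1449517619
female,93,0.1721638461,0.1581587706
female,94,0.1892816344,0.1724465936
female,95,0.2081053618,0.1878785344
female,96,0.2288050404,0.2045163945
female,97,0.2515676252,0.2224191283
female,98,0.2765987032,0.241641237
female,99,0.3041243498,0.2622308807
female,100,0.3343931707,0.2842276938
female,101,0.3676785478,0.3076602999
female,102,0.4042811073,0.332543532
female,103,0.4445314361,0.3588753865
female,104,0.4887930666,0.3866337601
female,105,0.5374657604,0.415773051
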