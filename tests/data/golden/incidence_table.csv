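# config_hash=2de40eb911b254e9
# seed=0
sex,age_band,n,py,rate,ci_low,ci_high,display,scope
male,40-44,3,39000,7.692307692,1.586338777,22.48018736,7.7 (1.6–22.5),all
male,45-49,5,32250,15.50387597,5.034066326,36.18087466,15.5 (5.0–36.2),all
male,50-54,7,25500,27.45098039,11.03671785,56.55951122,27.5 (11.0–56.6),all
male,55-59,10,18300,54.64480874,26.20430981,100.4937489,54.6 (26.2–100.5),all
male,60-64,10,12300,81.30081301,38.98689997,149.5150898,81.3 (39.0–149.5),all
male,65-69,13,7050,184.3971631,98.18372328,315.3247648,184.4 (98.2–315.3),all
male,70-74,15,3900,384.6153846,215.2663111,634.3645864,384.6 (215.3–634.4),all
male,75-79,12,2100,571.4285714,295.2654814,998.1707166,571.4 (295.3–998.2),all
male,80+,20,1500,1333.333333,814.434639,2059.225194,1333.3 (814.4–2059.2),all
female,40-44,6,39000,15.38461538,5.645882701,33.48583083,15.4 (5.6–33.5),all
female,45-49,5,32250,15.50387597,5.034066326,36.18087466,15.5 (5.0–36.2),all
female,50-54,5,25500,19.60784314,6.366613295,45.75816502,19.6 (6.4–45.8),all
female,55-59,10,18300,54.64480874,26.20430981,100.4937489,54.6 (26.2–100.5),all
female,60-64,8,12300,65.04065041,28.0799364,128.1560099,65.0 (28.1–128.2),all
female,65-69,18,7050,255.3191489,151.3183089,403.51433,255.3 (151.3–403.5),all
female,70-74,12,3900,307.6923077,158.9891054,537.4765397,307.7 (159.0–537.5),all
female,75-79,19,2100,904.7619048,544.7257697,1412.897789,904.8 (544.7–1412.9),all
female,80+,21,1500,1400,866.6220656,2140.048716,1400.0 (866.6–2140.0),all
male,40-44,1,9000,11.11111111,0.2813089776,61.90714879,11.1 (0.3–61.9),national
male,45-49,3,8250,36.36363636,7.499056035,106.2699766,36.4 (7.5–106.3),national
male,50-54,1,7500,13.33333333,0.3375707731,74.28857855,13.3 (0.3–74.3),national
male,55-59,1,6300,15.87301587,0.401869968,88.43878398,15.9 (0.4–88.4),national
male,60-64,2,4800,41.66666667,5.046026636,150.5143264,41.7 (5.0–150.5),national
male,65-69,4,3300,121.2121212,33.02622344,310.351172,121.2 (33.0–310.4),national
male,70-74,10,2100,476.1904762,228.3518427,875.7312401,476.2 (228.4–875.7),national
male,75-79,3,1200,250,51.55601024,730.6060891,250.0 (51.6–730.6),national
male,80+,10,900,1111.111111,532.8209662,2043.372894,1111.1 (532.8–2043.4),national
female,40-44,2,9000,22.22222222,2.691214206,80.27430742,22.2 (2.7–80.3),national
female,45-49,1,8250,12.12121212,0.306882521,67.53507141,12.1 (0.3–67.5),national
female,50-54,2,7500,26.66666667,3.229457047,96.3291689,26.7 (3.2–96.3),national
female,55-59,4,6300,63.49206349,17.29945038,162.5648996,63.5 (17.3–162.6),national
female,60-64,3,4800,62.5,12.88900256,182.6515223,62.5 (12.9–182.7),national
female,65-69,9,3300,272.7272727,124.7082757,517.7213167,272.7 (124.7–517.7),national
female,70-74,5,2100,238.0952381,77.30887572,555.6348609,238.1 (77.3–555.6),national
female,75-79,10,1200,833.3333333,399.6157247,1532.52967,833.3 (399.6–1532.5),national
female,80+,9,900,1000,457.2636775,1898.311495,1000.0 (457.3–1898.3),national
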