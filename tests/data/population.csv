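# synthetic fixture: generated by fraxkit.synthetic, seed=4242, half-size default populations
year,sex,nationality,age_band,count
2017,male,national,40-44,3000
2017,male,national,45-49,2750
2017,male,national,50-54,2500
2017,male,national,55-59,2100
2017,male,national,60-64,1600
2017,male,national,65-69,1100
2017,male,national,70-74,700
2017,male,national,75-79,400
2017,male,national,80+,300
2017,male,expatriate,40-44,10000
2017,male,expatriate,45-49,8000
2017,male,expatriate,50-54,6000
2017,male,expatriate,55-59,4000
2017,male,expatriate,60-64,2500
2017,male,expatriate,65-69,1250
2017,male,expatriate,70-74,600
2017,male,expatriate,75-79,300
2017,male,expatriate,80+,200
2017,female,national,40-44,3000
2017,female,national,45-49,2750
2017,female,national,50-54,2500
2017,female,national,55-59,2100
2017,female,national,60-64,1600
2017,female,national,65-69,1100
2017,female,national,70-74,700
2017,female,national,75-79,400
2017,female,national,80+,300
2017,female,expatriate,40-44,10000
2017,female,expatriate,45-49,8000
2017,female,expatriate,50-54,6000
2017,female,expatriate,55-59,4000
2017,female,expatriate,60-64,2500
2017,female,expatriate,65-69,1250
2017,female,expatriate,70-74,600
2017,female,expatriate,75-79,300
2017,female,expatriate,80+,200
2018,male,national,40-44,3000
2018,male,national,45-49,2750
2018,male,national,50-54,2500
2018,male,national,55-59,2100
2018,male,national,60-64,1600
2018,male,national,65-69,1100
2018,male,national,70-74,700
2018,male,national,75-79,400
2018,male,national,80+,300
2018,male,expatriate,40-44,10000
2018,male,expatriate,45-49,8000
2018,male,expatriate,50-54,6000
2018,male,expatriate,55-59,4000
2018,male,expatriate,60-64,2500
2018,male,expatriate,65-69,1250
2018,male,expatriate,70-74,600
2018,male,expatriate,75-79,300
2018,male,expatriate,80+,200
2018,female,national,40-44,3000
2018,female,national,45-49,2750
2018,female,national,50-54,2500
2018,female,national,55-59,2100
2018,female,national,60-64,1600
2018,female,national,65-69,1100
2018,female,national,70-74,700
2018,female,national,75-79,400
2018,female,national,80+,300
2018,female,expatriate,40-44,10000
2018,female,expatriate,45-49,8000
2018,female,expatriate,50-54,6000
2018,female,expatriate,55-59,4000
2018,female,expatriate,60-64,2500
2018,female,expatriate,65-69,1250
2018,female,expatriate,70-74,600
2018,female,expatriate,75-79,300
2018,female,expatriate,80+,200
2019,male,national,40-44,3000
2019,male,national,45-49,2750
2019,male,national,50-54,2500
2019,male,national,55-59,2100
2019,male,national,60-64,1600
2019,male,national,65-69,1100
2019,male,national,70-74,700
2019,male,national,75-79,400
2019,male,national,80+,300
2019,male,expatriate,40-44,10000
2019,male,expatriate,45-49,8000
2019,male,expatriate,50-54,6000
2019,male,expatriate,55-59,4000
2019,male,expatriate,60-64,2500
2019,male,expatriate,65-69,1250
2019,male,expatriate,70-74,600
2019,male,expatriate,75-79,300
2019,male,expatriate,80+,200
2019,female,national,40-44,3000
2019,female,national,45-49,2750
2019,female,national,50-54,2500
2019,female,national,55-59,2100
2019,female,national,60-64,1600
2019,female,national,65-69,1100
2019,female,national,70-74,700
2019,female,national,75-79,400
2019,female,national,80+,300
2019,female,expatriate,40-44,10000
2019,female,expatriate,45-49,8000
2019,female,expatriate,50-54,6000
2019,female,expatriate,55-59,4000
2019,female,expatriate,60-64,2500
2019,female,expatriate,65-69,1250
2019,female,expatriate,70-74,600
2019,female,expatriate,75-79,300
2019,female,expatriate,80+,200
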