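record,zero_crossings,tw_length,heart_rate,twa_quantification,result
twa01,31,103,103,375.62,Detected
twa06,35,123,123,150.68,Detected
twa09,17,131,131,152.21,Detected
twa13,0,130,130,18.99,Detected
twa15,48,110,110,0,Non-detected
twa17,45,124,124,0,Non-detected
twa21,29,126,126,147.5,Detected
twa25,4,122,122,2.76,Detected
twa28,50,107,107,0,Non-detected
twa29,41,131,131,373.89,Detected
twa30,45,132,132,148.84,Detected
twa33,59,126,126,0,Non-detected
twa34,18,127,127,2.061,Detected
twa35,41,133,133,1.726,Detected
twa50,34,127,127,1.375,Detected
twa51,39,130,130,1.374,Detected
twa64,29,126,126,1.374,Detected
twa67,37,128,128,147.764,Detected
twa69,38,103,103,0,Non-detected
twa70,24,123,123,148.095,Detected
twa72,0,133,133,6.226,Detected
twa73,1,124,124,5.186,Detected
twa76,34,125,125,1.374,Detected
twa78,54,126,126,0,Non-detected
twa79,33,134,134,3.436,Detected
twa82,3,130,130,3.453,Detected
twa88,42,106,106,0,Non-detected
twa91,43,110,110,0,Non-detected
twa97,60,126,126,0,Non-detected
twa98,59,126,126,0,Non-detected
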