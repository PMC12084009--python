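id,group,gender,age,logmar,deprivation_duration,time_since_surgery
CC1,CC,Male,17.0,0.17,0.2,16.8
CC2,CC,Male,43.5,0.9,20.8,22.7
CC3,CC,Male,18.7,0.9,15.6,3.1
CC4,CC,Male,15.2,0.62,7.0,8.2
CC5,CC,Male,32.4,0.88,14.0,18.4
CC6,CC,Male,23.9,0.78,6.0,17.9
CC7,CC,Male,13.1,0.54,0.8,12.4
CC8,CC,Male,18.3,0.66,16.4,1.9
CC9,CC,Male,36.9,1.34,6.0,30.9
CC10,CC,Female,38.8,1.04,31.4,7.4
SC1,SC,Male,17.7,0.2,,
SC2,SC,Male,41.9,-0.27,,
SC3,SC,Male,19.5,-0.25,,
SC4,SC,Male,16.0,-0.11,,
SC5,SC,Male,33.3,-0.12,,
SC6,SC,Male,24.0,-0.16,,
SC7,SC,Male,12.2,-0.25,,
SC8,SC,Female,25.1,-0.28,,
SC9,SC,Female,36.0,-0.21,,
SC10,SC,Male,37.3,-0.22,,
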