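time,state:extreme_weather_climate_event,indicator:fraction:decreased_water,indicator:fraction:farm_closures_widespread,indicator:fraction:season_yield_collapse
0.0,0,0.05,0.0,0.0
1.0,0,0.05,0.0,0.0
2.0,0,0.05,0.0,0.0
3.0,0,0.05,0.0,0.0
4.0,0,0.05,0.0,0.0
5.0,0,0.05,0.0,0.0
6.0,0,0.05,0.0,0.0
7.0,0,0.05,0.0,0.0
8.0,0,0.05,0.0,0.0
9.0,0,0.05,0.0,0.0
10.0,0,0.05,0.0,0.0
11.0,0,0.05,0.0,0.0
12.0,1,0.35,0.0,0.12
13.0,1,0.35,0.0,0.12
14.0,1,0.35,0.0,0.12
15.0,1,0.35,0.0,0.12
16.0,1,0.35,0.0,0.12
17.0,1,0.35,0.0,0.12
18.0,1,0.35,0.0,0.12
19.0,1,0.35,0.0,0.12
20.0,1,0.35,0.0,0.12
21.0,1,0.35,0.0,0.12
22.0,1,0.35,0.0,0.12
23.0,1,0.35,0.0,0.12
24.0,1,0.35,0.0,0.12
25.0,1,0.35,0.0,0.12
26.0,1,0.35,0.0,0.12
27.0,1,0.35,0.0,0.12
28.0,1,0.35,0.0,0.12
29.0,1,0.35,0.0,0.12
30.0,1,0.35,0.0,0.12
31.0,1,0.35,0.0,0.12
32.0,1,0.35,0.0,0.12
33.0,1,0.35,0.0,0.12
34.0,1,0.35,0.0,0.12
35.0,1,0.35,0.0,0.12
36.0,1,0.35,0.0,0.12
37.0,1,0.35,0.0,0.12
38.0,1,0.35,0.0,0.12
39.0,1,0.35,0.0,0.12
40.0,1,0.35,0.0,0.12
41.0,1,0.35,0.0,0.12
42.0,1,0.35,0.0,0.12
43.0,1,0.35,0.0,0.12
44.0,1,0.35,0.0,0.12
45.0,1,0.35,0.0,0.12
46.0,1,0.35,0.0,0.12
47.0,1,0.35,0.0,0.12
48.0,1,0.35,0.0,0.12
49.0,1,0.35,0.0,0.12
50.0,1,0.35,0.0,0.12
51.0,0,0.1,0.0,0.0
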