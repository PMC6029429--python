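time,state:delivery_truck_access_blocked,indicator:fraction:roads_are_obstructed,indicator:fraction:transit_service_suspended
-48.0,1,1.0,0.0
-47.0,1,1.0,0.0
-46.0,1,1.0,0.0
-45.0,1,1.0,0.0
-44.0,1,1.0,0.0
-43.0,1,1.0,0.0
-42.0,1,1.0,0.0
-41.0,1,1.0,0.0
-40.0,1,1.0,0.0
-39.0,1,1.0,0.0
-38.0,1,1.0,0.0
-37.0,1,1.0,0.0
-36.0,1,1.0,0.0
-35.0,1,1.0,0.0
-34.0,1,1.0,0.0
-33.0,1,1.0,0.0
-32.0,1,1.0,0.0
-31.0,1,1.0,0.0
-30.0,1,1.0,0.0
-29.0,1,1.0,0.0
-28.0,1,1.0,0.0
-27.0,1,1.0,0.0
-26.0,1,1.0,0.0
-25.0,1,1.0,0.0
-24.0,1,1.0,0.0
-23.0,1,1.0,0.0
-22.0,1,1.0,0.0
-21.0,1,1.0,0.0
-20.0,1,1.0,0.0
-19.0,1,1.0,0.0
-18.0,1,1.0,0.0
-17.0,1,1.0,0.0
-16.0,1,1.0,0.0
-15.0,1,1.0,0.0
-14.0,1,1.0,0.0
-13.0,1,1.0,0.0
-12.0,1,1.0,0.0
-11.0,1,1.0,0.0
-10.0,1,1.0,0.0
-9.0,1,1.0,0.0
-8.0,1,1.0,0.0
-7.0,1,1.0,0.0
-6.0,1,1.0,0.0
-5.0,1,1.0,0.0
-4.0,1,1.0,0.0
-3.0,1,1.0,0.0
-2.0,1,1.0,0.0
-1.0,1,1.0,0.0
0.0,1,1.0,0.0
1.0,1,1.0,0.25
2.0,1,1.0,0.25
3.0,1,1.0,0.25
4.0,1,1.0,0.25
5.0,1,1.0,0.25
6.0,1,1.0,0.25
7.0,1,1.0,0.25
8.0,1,1.0,0.25
9.0,1,1.0,0.25
10.0,1,1.0,0.25
11.0,1,1.0,0.25
12.0,1,1.0,0.25
13.0,1,1.0,0.25
14.0,1,1.0,0.25
15.0,1,1.0,0.25
16.0,1,1.0,0.25
17.0,1,1.0,0.25
18.0,1,1.0,0.25
19.0,1,1.0,0.25
20.0,1,1.0,0.25
21.0,1,1.0,0.25
22.0,1,1.0,0.25
23.0,1,1.0,0.25
24.0,1,1.0,0.5
25.0,1,1.0,0.5
26.0,1,1.0,0.5
27.0,1,1.0,0.5
28.0,1,1.0,0.5
29.0,1,1.0,0.5
30.0,1,1.0,0.5
31.0,1,1.0,0.5
32.0,1,1.0,0.5
33.0,1,1.0,0.5
34.0,1,1.0,0.5
35.0,1,1.0,0.5
36.0,1,1.0,0.5
37.0,1,1.0,0.5
38.0,1,1.0,0.5
39.0,1,1.0,0.5
40.0,1,1.0,0.5
41.0,1,1.0,0.5
42.0,1,1.0,0.5
43.0,1,1.0,0.5
44.0,1,1.0,0.5
45.0,1,1.0,0.5
46.0,1,1.0,0.5
47.0,1,1.0,0.5
48.0,1,1.0,0.75
49.0,1,1.0,0.75
50.0,1,1.0,0.75
51.0,1,1.0,0.75
52.0,1,1.0,0.75
53.0,1,1.0,0.75
54.0,1,1.0,0.75
55.0,1,1.0,0.75
56.0,1,1.0,0.75
57.0,1,1.0,0.75
58.0,1,1.0,0.75
59.0,1,1.0,0.75
60.0,1,1.0,0.75
61.0,1,1.0,0.75
62.0,1,1.0,0.75
63.0,1,1.0,0.75
64.0,1,1.0,0.75
65.0,1,1.0,0.75
66.0,1,1.0,0.75
67.0,1,1.0,0.75
68.0,1,1.0,0.75
69.0,1,1.0,0.75
70.0,1,1.0,0.75
71.0,1,1.0,0.75
72.0,1,1.0,0.9
73.0,1,1.0,0.9
74.0,1,1.0,0.9
75.0,1,1.0,0.9
76.0,1,1.0,0.9
77.0,1,1.0,0.9
78.0,1,1.0,0.9
79.0,1,1.0,0.9
80.0,1,1.0,0.9
81.0,1,1.0,0.9
82.0,1,1.0,0.9
83.0,1,1.0,0.9
84.0,1,1.0,0.9
85.0,1,1.0,0.9
86.0,1,1.0,0.9
87.0,1,1.0,0.9
88.0,1,1.0,0.9
89.0,1,1.0,0.9
90.0,1,1.0,0.9
91.0,1,1.0,0.9
92.0,1,1.0,0.9
93.0,1,1.0,0.9
94.0,1,1.0,0.9
95.0,1,1.0,0.9
96.0,1,1.0,1.0
97.0,1,1.0,1.0
98.0,1,1.0,1.0
99.0,1,1.0,1.0
100.0,1,1.0,1.0
101.0,1,1.0,1.0
102.0,1,1.0,1.0
103.0,1,1.0,1.0
104.0,1,1.0,1.0
105.0,1,1.0,1.0
106.0,1,1.0,1.0
107.0,1,1.0,1.0
108.0,1,1.0,1.0
109.0,1,1.0,1.0
110.0,1,1.0,1.0
111.0,1,1.0,1.0
112.0,1,1.0,1.0
113.0,1,1.0,1.0
114.0,1,1.0,1.0
115.0,1,1.0,1.0
116.0,1,1.0,1.0
117.0,1,1.0,1.0
118.0,1,1.0,1.0
119.0,1,1.0,1.0
120.0,1,0.15,1.0
121.0,1,0.15,1.0
122.0,1,0.15,1.0
123.0,1,0.15,1.0
124.0,1,0.15,1.0
125.0,1,0.15,1.0
126.0,1,0.15,1.0
127.0,1,0.15,1.0
128.0,1,0.15,1.0
129.0,1,0.15,1.0
130.0,1,0.15,1.0
131.0,1,0.15,1.0
132.0,1,0.15,1.0
133.0,1,0.15,1.0
134.0,1,0.15,1.0
135.0,1,0.15,1.0
136.0,1,0.15,1.0
137.0,1,0.15,1.0
138.0,1,0.15,1.0
139.0,1,0.15,1.0
140.0,1,0.15,1.0
141.0,1,0.15,1.0
142.0,1,0.15,1.0
143.0,1,0.15,1.0
144.0,1,0.15,1.0
145.0,1,0.15,1.0
146.0,1,0.15,1.0
147.0,1,0.15,1.0
148.0,1,0.15,1.0
149.0,1,0.15,1.0
150.0,1,0.15,1.0
151.0,1,0.15,1.0
152.0,1,0.15,1.0
153.0,1,0.15,1.0
154.0,1,0.15,1.0
155.0,1,0.15,1.0
156.0,1,0.15,1.0
157.0,1,0.15,1.0
158.0,1,0.15,1.0
159.0,1,0.15,1.0
160.0,1,0.15,1.0
161.0,1,0.15,1.0
162.0,1,0.15,1.0
163.0,1,0.15,1.0
164.0,1,0.15,1.0
165.0,1,0.15,1.0
166.0,1,0.15,1.0
167.0,1,0.15,1.0
168.0,1,0.15,1.0
169.0,1,0.15,1.0
170.0,1,0.15,1.0
171.0,1,0.15,1.0
172.0,1,0.15,1.0
173.0,1,0.15,1.0
174.0,1,0.15,1.0
175.0,1,0.15,1.0
176.0,1,0.15,1.0
177.0,1,0.15,1.0
178.0,1,0.15,1.0
179.0,1,0.15,1.0
180.0,1,0.15,1.0
181.0,1,0.15,1.0
182.0,1,0.15,1.0
183.0,1,0.15,1.0
184.0,1,0.15,1.0
185.0,1,0.15,1.0
186.0,1,0.15,1.0
187.0,1,0.15,1.0
188.0,1,0.15,1.0
189.0,1,0.15,1.0
190.0,1,0.15,1.0
191.0,1,0.15,1.0
192.0,1,0.15,1.0
193.0,1,0.15,1.0
194.0,1,0.15,1.0
195.0,1,0.15,1.0
196.0,1,0.15,1.0
197.0,1,0.15,1.0
198.0,1,0.15,1.0
199.0,1,0.15,1.0
200.0,1,0.15,1.0
201.0,1,0.15,1.0
202.0,1,0.15,1.0
203.0,1,0.15,1.0
204.0,1,0.15,1.0
205.0,1,0.15,1.0
206.0,1,0.15,1.0
207.0,1,0.15,1.0
208.0,1,0.15,1.0
209.0,1,0.15,1.0
210.0,1,0.15,1.0
211.0,1,0.15,1.0
212.0,1,0.15,1.0
213.0,1,0.15,1.0
214.0,1,0.15,1.0
215.0,1,0.15,1.0
216.0,0,0.0,1.0
217.0,0,0.0,1.0
218.0,0,0.0,1.0
219.0,0,0.0,1.0
220.0,0,0.0,1.0
221.0,0,0.0,1.0
222.0,0,0.0,1.0
223.0,0,0.0,1.0
224.0,0,0.0,1.0
225.0,0,0.0,1.0
226.0,0,0.0,1.0
227.0,0,0.0,1.0
228.0,0,0.0,1.0
229.0,0,0.0,1.0
230.0,0,0.0,1.0
231.0,0,0.0,1.0
232.0,0,0.0,1.0
233.0,0,0.0,1.0
234.0,0,0.0,1.0
235.0,0,0.0,1.0
236.0,0,0.0,1.0
237.0,0,0.0,1.0
238.0,0,0.0,1.0
239.0,0,0.0,1.0
240.0,0,0.0,1.0
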