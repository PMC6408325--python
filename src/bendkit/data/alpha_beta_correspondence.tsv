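# alpha_canonical	beta_canonical (generated by bendkit.annotation.build_correspondence_table)
1	1
2	2
3	3
4	4
5	5
6	6
7	7
8	8
9	9
10	10
11	11
12	12
13	13
14	14
15	15
16	16
17	17
18	18
19	19
20	20
21	21
22	22
23	23
24	24
25	25
26	26
27	27
28	28
29	29
30	30
31	31
32	32
33	33
34	34
35	35
36	36
37	37
38	38
39	39
40	40
41	41
42	42
45	43
46	44
47	45
48	46
49	47
50	48
51	49
52	50
53	51
54	52
55	53
56	54
57	55
58	56
59	57
60	58
61	59
62	60
63	61
64	62
65	63
66	64
67	65
68	66
69	67
70	68
71	69
72	70
73	71
74	72
75	73
76	74
77	75
78	76
79	77
80	78
81	79
82	80
83	81
84	82
85	83
86	84
87	85
88	86
89	87
90	88
91	89
92	90
93	91
94	92
95	93
96	94
97	95
98	96
99	97
100	98
101	99
102	100
103	101
104	102
105	103
106	104
107	105
108	106
109	107
110	108
111	109
112	110
113	111
114	112
115	113
116	114
117	115
118	116
119	117
120	118
121	119
122	120
123	121
124	122
125	123
126	124
127	125
128	126
129	127
130	128
131	129
132	130
133	131
134	132
135	133
136	134
137	135
138	136
139	137
140	138
141	139
142	140
143	141
144	142
145	143
146	144
147	145
148	146
149	147
150	148
151	149
152	150
153	151
154	152
155	153
156	154
157	155
158	156
159	157
160	158
161	159
162	160
163	161
164	162
165	163
166	164
167	165
168	166
169	167
170	168
171	169
172	170
173	171
174	172
175	173
176	174
177	175
178	176
179	177
180	178
181	179
182	180
183	181
184	182
185	183
186	184
187	185
188	186
189	187
190	188
191	189
192	190
193	191
194	192
195	193
196	194
197	195
198	196
199	197
200	198
201	199
202	200
203	201
204	202
205	203
206	204
207	205
208	206
209	207
210	208
211	209
212	210
213	211
214	212
215	213
216	214
217	215
218	216
219	217
220	218
221	219
222	220
223	221
224	222
225	223
226	224
227	225
228	226
229	227
230	228
231	229
232	230
233	231
234	232
235	233
236	234
237	235
238	236
239	237
240	238
241	239
242	240
243	241
244	242
245	243
246	244
247	245
248	246
249	247
250	248
251	249
252	250
253	251
254	252
255	253
256	254
257	255
258	256
259	257
260	258
261	259
262	260
263	261
264	262
265	263
266	264
267	265
268	266
269	267
270	268
271	269
272	270
273	271
274	272
275	273
276	274
277	275
278	276
279	277
280	278
281	279
282	280
283	281
284	282
285	283
286	284
287	285
288	286
289	287
290	288
291	289
292	290
293	291
294	292
295	293
296	294
297	295
298	296
299	297
300	298
301	299
302	300
303	301
304	302
305	303
306	304
307	305
308	306
309	307
310	308
311	309
312	310
313	311
314	312
315	313
316	314
317	315
318	316
319	317
320	318
321	319
322	320
323	321
324	322
325	323
326	324
327	325
328	326
329	327
330	328
331	329
332	330
333	331
334	332
335	333
336	334
337	335
338	336
339	337
340	338
341	339
342	340
343	341
344	342
345	343
346	344
347	345
348	346
349	347
350	348
351	349
352	350
353	351
354	352
355	353
356	354
357	355
358	356
359	357
360	358
369	359
370	360
371	361
372	362
373	363
374	364
375	365
376	366
377	367
378	368
379	369
380	370
381	371
382	372
383	373
384	374
385	375
386	376
387	377
388	378
389	379
390	380
391	381
392	382
393	383
394	384
395	385
396	386
397	387
398	388
399	389
400	390
401	391
402	392
403	393
404	394
405	395
406	396
407	397
408	398
409	399
410	400
411	401
412	402
413	403
414	404
415	405
416	406
417	407
418	408
419	409
420	410
421	411
422	412
423	413
424	414
425	415
426	416
427	417
428	418
429	419
430	420
431	421
432	422
433	423
434	424
435	425
437	426
438	427
439	428
440	429
441	430
442	431
443	432
444	433
445	434
446	435
447	436
448	437
449	438
450	439
451	440
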