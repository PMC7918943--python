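chrom	pos	ref	alt
1	22437150	G	T
1	50449203	C	G
1	62292980	A	T
1	105020894	T	C
1	106074552	A	G
1	110409182	A	G
1	174773501	A	G
1	177934776	G	A
1	179883114	C	T
1	201134152	T	G
1	240199383	C	G
10	3044656	A	G
10	5145271	C	A
10	9726207	G	T
10	28229502	T	C
10	30253955	C	G
10	35356003	C	G
10	37703897	C	T
10	39017676	C	G
10	46457534	A	C
10	62705246	G	A
10	89921297	T	G
10	98890747	T	C
10	121721893	C	G
10	121861745	A	C
10	131075302	C	A
11	8041343	C	T
11	29578873	A	G
11	30686015	C	A
11	35004519	A	C
11	38657041	T	G
11	58127919	G	A
11	67605073	C	G
11	68194825	C	A
11	76060362	G	T
11	97702674	A	C
11	110515447	A	G
11	121475689	C	T
11	125749806	C	G
11	130649934	T	A
12	11416256	T	A
12	17196906	C	A
12	25732731	C	T
12	34219760	A	G
12	38122320	C	T
12	42011339	G	C
12	47700937	T	A
12	49007235	A	C
12	66699289	C	G
12	70717879	C	A
12	74397758	A	C
12	77310043	A	G
12	106914536	C	A
12	110038759	T	G
12	111558323	T	A
12	115948963	T	C
12	120635301	A	T
13	1771391	G	A
13	5464105	A	G
13	19798766	C	T
13	24906057	T	C
13	36106739	C	G
13	37187762	G	T
13	39296619	G	T
13	41863660	G	T
13	45964725	T	G
13	57348529	G	A
13	85852565	A	C
13	92451916	G	C
13	103639356	G	T
13	108848125	G	A
13	109697039	T	C
14	10435126	A	T
14	15948681	C	G
14	24561210	C	A
14	27236388	G	A
14	34520505	A	T
14	44733329	T	G
14	46557812	A	T
14	60879222	G	C
14	72093320	T	G
14	84250639	G	T
14	104470704	A	C
14	105348233	G	A
15	4975180	C	G
15	13478046	C	G
15	21546215	G	T
15	23027053	G	A
15	38010749	T	C
15	46744325	A	T
15	65151920	G	A
15	65672090	C	T
15	92949993	G	C
15	93001382	C	T
16	4621872	A	T
16	9801823	T	G
16	10266577	G	T
16	10808458	T	G
16	12201766	G	T
16	13104222	T	A
16	23460712	G	T
16	23658496	C	A
16	25069680	T	C
16	30064255	C	A
16	36598850	A	T
16	36637409	A	T
16	37414907	T	G
16	38368564	C	T
16	41442978	G	A
16	47517839	C	T
16	56291957	T	A
16	62124036	G	T
16	62300952	T	G
16	68270478	A	C
16	72542053	T	G
16	73825800	T	G
17	8591991	C	T
17	17658505	A	T
17	35669669	G	C
17	39495506	T	C
17	45041227	G	A
17	50472123	C	T
17	50895861	G	T
17	55578126	A	G
17	56364521	T	C
17	56420716	C	T
17	65312647	A	G
17	66080697	A	T
17	72830133	A	G
17	78940460	G	T
17	79848370	T	A
18	11435007	G	C
18	15610584	G	A
18	16011401	C	G
18	30685593	G	A
18	35402538	G	T
18	40167642	A	G
18	50595864	A	T
18	54545575	A	G
18	55965946	G	A
18	69330754	G	C
18	72964967	G	A
18	73472266	T	A
19	3504788	T	A
19	10893546	C	G
19	11846360	G	T
19	16571348	C	A
19	18458695	C	A
19	23948539	T	G
19	24630400	C	G
19	27904425	A	C
19	34301074	C	G
19	42202926	T	C
19	43159800	G	C
19	45850247	T	G
19	52336843	T	A
19	52487635	C	G
19	52895905	A	T
19	53080573	A	T
19	53304797	G	A
19	54518604	T	C
2	20581237	A	C
2	22049396	G	C
2	40313147	C	G
2	43875672	T	A
2	66347344	T	C
2	77521244	A	C
2	87010321	G	A
2	94380451	T	G
2	139320437	G	T
2	140905286	G	C
2	172468898	A	T
2	194997245	G	T
2	199852902	T	G
2	200448476	C	T
20	3112399	G	A
20	3867788	A	G
20	20909417	G	C
20	28788957	C	G
20	40825517	C	T
20	57978941	T	C
21	4019857	G	A
21	9976905	A	C
21	14278041	A	C
21	16004504	C	A
21	20969188	C	G
21	21421458	T	A
21	23170624	G	T
21	33989098	A	G
21	38151735	G	A
21	45951055	C	A
22	8533803	A	T
22	20392361	G	C
22	25280595	A	G
22	39387190	C	T
3	3989818	T	C
3	9716682	G	A
3	16606860	T	A
3	20054560	A	T
3	45405522	C	T
3	70396741	C	T
3	83677458	A	G
3	101500442	A	T
3	150661697	G	T
3	154231268	T	G
3	161235261	T	C
3	171128428	T	G
3	185439449	G	C
3	185759896	A	T
4	12133539	C	T
4	28101720	A	G
4	59578256	G	T
4	59783227	T	G
4	64496502	T	G
4	97086656	T	C
4	101841725	G	T
4	127732828	A	C
4	138023622	C	G
4	145859302	T	G
4	163406548	G	C
4	179116410	C	A
5	11580506	T	A
5	34447719	A	T
5	37500312	T	C
5	42128054	T	C
5	51659484	C	G
5	78762197	C	T
5	78933183	A	C
5	84418603	T	C
5	93517903	T	G
5	94283864	T	C
5	94976821	G	C
5	99702499	A	T
5	100804914	C	A
5	112109006	A	G
5	136861186	T	G
5	173026215	G	C
5	174389152	T	C
5	175221885	T	A
6	2190869	A	G
6	13801138	T	C
6	22607827	G	T
6	32995787	G	T
6	39094573	G	A
6	39471172	A	G
6	50189177	C	A
6	52025321	A	C
6	58857711	A	G
6	79993573	A	G
6	94002512	C	A
6	101730174	G	C
6	115660352	T	C
6	136325259	A	C
6	152399578	T	C
6	169092764	G	A
7	2374565	A	T
7	25183172	T	A
7	92702164	C	A
7	97915069	C	G
7	111386041	C	A
7	115149878	T	C
7	147466904	G	C
8	41089243	G	C
8	88504033	A	C
8	106821737	C	A
8	116603386	A	C
8	123972566	G	A
8	129480080	C	G
8	142131982	C	G
9	3205940	C	G
9	3438073	T	A
9	23629282	G	A
9	39366425	G	A
9	47781566	T	A
9	69662336	C	A
9	72878403	G	T
9	75321821	C	T
9	79702081	C	A
9	82523852	T	G
9	127478161	C	G
9	128456952	G	T
9	132681160	G	A
9	136394976	T	A
X	1807784	A	G
X	27753184	G	C
X	32850368	A	T
X	50637498	G	T
X	53057875	T	G
X	59432348	G	A
X	67054352	C	A
X	76778634	A	C
X	76800489	T	A
X	114829196	C	G
X	118591013	A	G
X	122108737	G	T
X	139099786	A	T
X	145625101	C	G
X	150395907	G	A
X	152325278	T	C
X	153395688	G	A
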