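pair_id	MAPK_adjacent	MAPK_tumor	TGFB_adjacent	TGFB_tumor
1	40.1	58.4	31.5	37.1
2	15.3	58.1	34.1	54.1
3	32.5	54.8	26.5	38.0
4	40.7	53.7	46.7	52.2
5	38.6	51.6	37.9	54.2
6	20.2	50.8	25.7	38.3
7	37.3	49.6	21.3	49.7
8	36.9	49.5	31.3	53.0
9	22.9	49.3	44.2	41.8
10	39.7	47.2	43.4	22.7
11	39.6	47.1	42.6	53.0
12	35.9	46.1	28.4	31.3
13	33.1	42.5	36.4	28.8
14	41.8	41.1	43.0	40.0
15	14.0	38.2	27.9	40.7
16	37.2	34.0	18.2	22.5
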