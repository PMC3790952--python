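position	carbon_type	delta_C	delta_H
1	CH-O	72.6	3.35
2	C	38.0
3	CH2	39.0	2.30;1.68
4	CH=	120.8	5.16
5	C=	135.3
6	CH2	38.7	2.11;2.07
7	CH2	24.4	2.22;2.16
8	CH=	124.4	4.94
9	C=	134.2
10	CH2	39.2	2.07
11	CH2	24.7	2.16;2.07
12	CH=	125.5	5.05
13	C=	134.0
14	CH2	35.1	2.19;1.99
15	CH2	27.4	1.55;1.28
16	CH3	24.0	0.83
17	CH3	22.9	0.87
18	CH3	16.5	1.61
19	CH3	16.1	1.54
20	CH3	16.0	1.58
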