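# Synthetic abridged life table, females, constructed to match recent
# Dutch female period mortality (life expectancy at birth ~83.5 y).
# Columns: exact age (years), annual probability of death q(x).
# q(x) between tabulated ages is obtained by log-linear interpolation;
# survival is forced to zero at age 110.
# age	qx
0	0.00310
1	0.00020
5	0.00007
10	0.00008
15	0.00015
20	0.00020
25	0.00025
30	0.00030
35	0.00050
40	0.00080
45	0.00130
50	0.00200
55	0.00300
60	0.00500
65	0.00800
70	0.01300
75	0.02300
80	0.04400
85	0.08500
90	0.16000
95	0.28000
100	0.42000
105	0.60000
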