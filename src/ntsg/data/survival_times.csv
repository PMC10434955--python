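time
79.05
46.12
43.01
36.66
34.26
32.15
26.31
25.82
25.74
23.63
22.69
21.73
20.28
19.13
18.10
17.36
17.14
17.12
16.62
15.96
14.83
14.77
14.76
14.24
13.80
13.29
13.11
12.63
12.07
12.03
12.02
11.98
11.79
11.64
11.25
10.75
9.47
9.22
9.02
8.66
8.65
8.53
8.37
8.26
10.06
9.74
5.17
7.66
7.63
7.62
7.59
7.39
7.32
7.28
7.26
7.09
6.97
6.94
6.93
6.76
6.54
6.25
5.85
5.71
5.62
1.05
10.34
7.93
7.87
5.41
5.41
5.34
5.32
5.32
5.09
5.06
4.98
4.87
4.51
4.50
4.40
4.34
4.33
1.19
1.26
10.66
5.49
4.26
4.23
4.18
3.88
3.82
3.70
3.64
3.57
3.52
3.48
3.36
3.36
3.31
3.25
3.02
2.87
2.83
2.75
2.69
2.69
2.64
2.62
2.54
2.46
2.26
2.23
2.09
2.07
2.02
2.02
1.76
1.46
1.40
1.35
0.90
0.81
0.51
0.50
0.40
0.20
0.08
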