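subject_id,dose_group,scan,region,bp_nd
1,20 mg,baseline,Ca,1.22
1,20 mg,baseline,Pu,2.15
1,20 mg,baseline,VSt,2.49
1,20 mg,baseline,SN,1.12
1,20 mg,baseline,GP,1.89
1,20 mg,amph,Ca,1.08
1,20 mg,amph,Pu,1.77
1,20 mg,amph,VSt,1.85
1,20 mg,amph,SN,0.66
1,20 mg,amph,GP,1.54
1,20 mg,amph_tak,Ca,0.94
1,20 mg,amph_tak,Pu,1.87
1,20 mg,amph_tak,VSt,1.99
1,20 mg,amph_tak,SN,0.99
1,20 mg,amph_tak,GP,1.49
2,20 mg,baseline,Ca,1.47
2,20 mg,baseline,Pu,2.17
2,20 mg,baseline,VSt,2.53
2,20 mg,baseline,SN,1.04
2,20 mg,baseline,GP,2.41
2,20 mg,amph,Ca,1.15
2,20 mg,amph,Pu,1.60
2,20 mg,amph,VSt,1.57
2,20 mg,amph,SN,0.70
2,20 mg,amph,GP,2.01
2,20 mg,amph_tak,Ca,1.17
2,20 mg,amph_tak,Pu,1.65
2,20 mg,amph_tak,VSt,1.72
2,20 mg,amph_tak,SN,0.67
2,20 mg,amph_tak,GP,1.89
3,20 mg,baseline,Ca,1.70
3,20 mg,baseline,Pu,2.29
3,20 mg,baseline,VSt,2.65
3,20 mg,baseline,SN,0.99
3,20 mg,baseline,GP,1.93
3,20 mg,amph,Ca,1.29
3,20 mg,amph,Pu,1.61
3,20 mg,amph,VSt,1.96
3,20 mg,amph,SN,0.75
3,20 mg,amph,GP,1.55
3,20 mg,amph_tak,Ca,1.27
3,20 mg,amph_tak,Pu,1.62
3,20 mg,amph_tak,VSt,1.91
3,20 mg,amph_tak,SN,0.64
3,20 mg,amph_tak,GP,1.57
4,20 mg,baseline,Ca,0.98
4,20 mg,baseline,Pu,2.00
4,20 mg,baseline,VSt,2.20
4,20 mg,baseline,SN,0.97
4,20 mg,baseline,GP,2.03
4,20 mg,amph,Ca,0.84
4,20 mg,amph,Pu,1.56
4,20 mg,amph,VSt,1.80
4,20 mg,amph,SN,0.72
4,20 mg,amph,GP,1.69
4,20 mg,amph_tak,Ca,0.92
4,20 mg,amph_tak,Pu,1.64
4,20 mg,amph_tak,VSt,1.92
4,20 mg,amph_tak,SN,0.84
4,20 mg,amph_tak,GP,1.70
5,20 mg,baseline,Ca,1.59
5,20 mg,baseline,Pu,2.24
5,20 mg,baseline,VSt,2.44
5,20 mg,baseline,SN,1.02
5,20 mg,baseline,GP,2.55
5,20 mg,amph,Ca,1.32
5,20 mg,amph,Pu,1.74
5,20 mg,amph,VSt,1.97
5,20 mg,amph,SN,0.85
5,20 mg,amph,GP,2.14
5,20 mg,amph_tak,Ca,1.38
5,20 mg,amph_tak,Pu,1.88
5,20 mg,amph_tak,VSt,2.02
5,20 mg,amph_tak,SN,0.95
5,20 mg,amph_tak,GP,2.23
6,40 mg,baseline,Ca,1.63
6,40 mg,baseline,Pu,2.17
6,40 mg,baseline,VSt,2.75
6,40 mg,baseline,SN,1.36
6,40 mg,baseline,GP,2.37
6,40 mg,amph,Ca,1.31
6,40 mg,amph,Pu,1.64
6,40 mg,amph,VSt,1.67
6,40 mg,amph,SN,0.70
6,40 mg,amph,GP,2.02
6,40 mg,amph_tak,Ca,1.44
6,40 mg,amph_tak,Pu,1.82
6,40 mg,amph_tak,VSt,1.76
6,40 mg,amph_tak,SN,0.92
6,40 mg,amph_tak,GP,2.37
7,40 mg,baseline,Ca,0.57
7,40 mg,baseline,Pu,1.69
7,40 mg,baseline,VSt,2.35
7,40 mg,baseline,SN,1.06
7,40 mg,baseline,GP,2.41
7,40 mg,amph,Ca,0.49
7,40 mg,amph,Pu,1.27
7,40 mg,amph,VSt,1.61
7,40 mg,amph,SN,0.77
7,40 mg,amph,GP,2.05
7,40 mg,amph_tak,Ca,0.52
7,40 mg,amph_tak,Pu,1.39
7,40 mg,amph_tak,VSt,1.82
7,40 mg,amph_tak,SN,0.86
7,40 mg,amph_tak,GP,2.15
8,40 mg,baseline,Ca,0.90
8,40 mg,baseline,Pu,2.06
8,40 mg,baseline,VSt,2.39
8,40 mg,baseline,SN,1.28
8,40 mg,baseline,GP,2.53
8,40 mg,amph,Ca,0.82
8,40 mg,amph,Pu,1.82
8,40 mg,amph,VSt,1.93
8,40 mg,amph,SN,0.93
8,40 mg,amph,GP,1.91
8,40 mg,amph_tak,Ca,0.85
8,40 mg,amph_tak,Pu,1.93
8,40 mg,amph_tak,VSt,2.04
8,40 mg,amph_tak,SN,1.31
8,40 mg,amph_tak,GP,2.18
9,40 mg,baseline,Ca,1.55
9,40 mg,baseline,Pu,2.19
9,40 mg,baseline,VSt,2.72
9,40 mg,baseline,SN,1.43
9,40 mg,baseline,GP,2.12
9,40 mg,amph,Ca,1.44
9,40 mg,amph,Pu,1.82
9,40 mg,amph,VSt,2.10
9,40 mg,amph,SN,1.16
9,40 mg,amph,GP,2.20
9,40 mg,amph_tak,Ca,1.42
9,40 mg,amph_tak,Pu,1.93
9,40 mg,amph_tak,VSt,2.10
9,40 mg,amph_tak,SN,1.04
9,40 mg,amph_tak,GP,2.12
10,40 mg,baseline,Ca,1.09
10,40 mg,baseline,Pu,1.80
10,40 mg,baseline,VSt,2.23
10,40 mg,baseline,SN,0.80
10,40 mg,baseline,GP,1.98
10,40 mg,amph,Ca,0.89
10,40 mg,amph,Pu,1.43
10,40 mg,amph,VSt,1.68
10,40 mg,amph,SN,0.69
10,40 mg,amph,GP,1.56
10,40 mg,amph_tak,Ca,0.95
10,40 mg,amph_tak,Pu,1.59
10,40 mg,amph_tak,VSt,1.97
10,40 mg,amph_tak,SN,0.77
10,40 mg,amph_tak,GP,1.82
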