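education,age,correction
5,20,-0.10
5,25,0.06
5,30,0.21
5,35,0.32
5,40,0.42
5,45,0.51
5,50,0.59
5,55,0.67
5,60,0.73
5,65,0.79
5,70,0.85
5,75,0.90
5,80,0.95
5,85,1.00
8,20,-0.35
8,25,-0.18
8,30,-0.05
8,35,0.07
8,40,0.17
8,45,0.26
8,50,0.34
8,55,0.42
8,60,0.48
8,65,0.54
8,70,0.60
8,75,0.65
8,80,0.70
8,85,0.75
13,20,-0.68
13,25,-0.51
13,30,-0.37
13,35,-0.26
13,40,-0.15
13,45,-0.07
13,50,0.02
13,55,0.09
13,60,0.15
13,65,0.22
13,70,0.27
13,75,0.32
13,80,0.37
13,85,0.42
16,25,-0.68
16,30,-0.54
16,35,-0.42
16,40,-0.32
16,45,-0.23
16,50,-0.15
16,55,-0.08
16,60,-0.01
16,65,0.05
16,70,0.10
16,75,0.16
16,80,0.21
16,85,0.25
18,25,-0.78
18,30,-0.64
18,35,-0.53
18,40,-0.42
18,45,-0.33
18,50,-0.25
18,55,-0.18
18,60,-0.12
18,65,-0.05
18,70,0.00
18,75,0.05
18,80,0.10
18,85,0.15
21,30,-0.79
21,35,-0.67
21,40,-0.57
21,45,-0.48
21,50,-0.40
21,55,-0.33
21,60,-0.26
21,65,-0.20
21,70,-0.14
21,75,-0.09
21,80,-0.04
21,85,0.01
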