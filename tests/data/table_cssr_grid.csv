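span,education,age,correction
2,5,20,0.48
2,5,25,0.52
2,5,30,0.56
2,5,35,0.59
2,5,40,0.62
2,5,45,0.65
2,5,50,0.68
2,5,55,0.70
2,5,60,0.73
2,5,65,0.75
2,5,70,0.78
2,5,75,0.80
2,5,80,0.82
2,5,85,0.84
2,8,20,0.36
2,8,25,0.40
2,8,30,0.43
2,8,35,0.47
2,8,40,0.50
2,8,45,0.52
2,8,50,0.55
2,8,55,0.58
2,8,60,0.60
2,8,65,0.63
2,8,70,0.65
2,8,75,0.67
2,8,80,0.69
2,8,85,0.71
2,13,20,0.23
2,13,25,0.27
2,13,30,0.30
2,13,35,0.33
2,13,40,0.36
2,13,45,0.39
2,13,50,0.42
2,13,55,0.45
2,13,60,0.47
2,13,65,0.49
2,13,70,0.52
2,13,75,0.54
2,13,80,0.56
2,13,85,0.58
2,16,25,0.21
2,16,30,0.24
2,16,35,0.28
2,16,40,0.31
2,16,45,0.34
2,16,50,0.36
2,16,55,0.39
2,16,60,0.41
2,16,65,0.44
2,16,70,0.46
2,16,75,0.48
2,16,80,0.50
2,16,85,0.52
2,18,25,0.18
2,18,30,0.21
2,18,35,0.25
2,18,40,0.28
2,18,45,0.30
2,18,50,0.33
2,18,55,0.36
2,18,60,0.38
2,18,65,0.41
2,18,70,0.43
2,18,75,0.45
2,18,80,0.47
2,18,85,0.49
2,21,30,0.17
2,21,35,0.20
2,21,40,0.23
2,21,45,0.26
2,21,50,0.29
2,21,55,0.32
2,21,60,0.34
2,21,65,0.36
2,21,70,0.39
2,21,75,0.41
2,21,80,0.43
2,21,85,0.45
3,5,20,0.29
3,5,25,0.33
3,5,30,0.36
3,5,35,0.39
3,5,40,0.42
3,5,45,0.45
3,5,50,0.48
3,5,55,0.51
3,5,60,0.53
3,5,65,0.55
3,5,70,0.58
3,5,75,0.60
3,5,80,0.62
3,5,85,0.64
3,8,20,0.16
3,8,25,0.20
3,8,30,0.23
3,8,35,0.27
3,8,40,0.30
3,8,45,0.33
3,8,50,0.35
3,8,55,0.38
3,8,60,0.40
3,8,65,0.43
3,8,70,0.45
3,8,75,0.47
3,8,80,0.49
3,8,85,0.51
3,13,20,0.03
3,13,25,0.07
3,13,30,0.10
3,13,35,0.13
3,13,40,0.17
3,13,45,0.19
3,13,50,0.22
3,13,55,0.25
3,13,60,0.27
3,13,65,0.29
3,13,70,0.32
3,13,75,0.34
3,13,80,0.36
3,13,85,0.38
3,16,25,0.01
3,16,30,0.05
3,16,35,0.08
3,16,40,0.11
3,16,45,0.14
3,16,50,0.16
3,16,55,0.19
3,16,60,0.22
3,16,65,0.24
3,16,70,0.26
3,16,75,0.28
3,16,80,0.30
3,16,85,0.33
3,18,25,-0.02
3,18,30,0.01
3,18,35,0.05
3,18,40,0.08
3,18,45,0.11
3,18,50,0.13
3,18,55,0.16
3,18,60,0.18
3,18,65,0.21
3,18,70,0.23
3,18,75,0.25
3,18,80,0.27
3,18,85,0.29
3,21,30,-0.03
3,21,35,0.00
3,21,40,0.04
3,21,45,0.06
3,21,50,0.09
3,21,55,0.12
3,21,60,0.14
3,21,65,0.17
3,21,70,0.19
3,21,75,0.21
3,21,80,0.23
3,21,85,0.25
4,5,20,0.14
4,5,25,0.18
4,5,30,0.22
4,5,35,0.25
4,5,40,0.28
4,5,45,0.31
4,5,50,0.34
4,5,55,0.36
4,5,60,0.39
4,5,65,0.41
4,5,70,0.44
4,5,75,0.46
4,5,80,0.48
4,5,85,0.50
4,8,20,0.02
4,8,25,0.06
4,8,30,0.09
4,8,35,0.12
4,8,40,0.16
4,8,45,0.18
4,8,50,0.21
4,8,55,0.24
4,8,60,0.26
4,8,65,0.29
4,8,70,0.31
4,8,75,0.33
4,8,80,0.35
4,8,85,0.37
4,13,20,-0.11
4,13,25,-0.08
4,13,30,-0.04
4,13,35,-0.01
4,13,40,0.02
4,13,45,0.05
4,13,50,0.08
4,13,55,0.11
4,13,60,0.13
4,13,65,0.15
4,13,70,0.18
4,13,75,0.20
4,13,80,0.22
4,13,85,0.24
4,16,25,-0.13
4,16,30,-0.10
4,16,35,-0.06
4,16,40,-0.03
4,16,45,-0.00
4,16,50,0.02
4,16,55,0.05
4,16,60,0.07
4,16,65,0.10
4,16,70,0.12
4,16,75,0.14
4,16,80,0.16
4,16,85,0.18
4,18,25,-0.16
4,18,30,-0.13
4,18,35,-0.09
4,18,40,-0.06
4,18,45,-0.04
4,18,50,-0.01
4,18,55,0.02
4,18,60,0.04
4,18,65,0.07
4,18,70,0.09
4,18,75,0.11
4,18,80,0.13
4,18,85,0.15
4,21,30,-0.17
4,21,35,-0.14
4,21,40,-0.11
4,21,45,-0.08
4,21,50,-0.05
4,21,55,-0.02
4,21,60,0.00
4,21,65,0.02
4,21,70,0.05
4,21,75,0.07
4,21,80,0.09
4,21,85,0.11
5,5,20,0.03
5,5,25,0.07
5,5,30,0.11
5,5,35,0.14
5,5,40,0.17
5,5,45,0.20
5,5,50,0.23
5,5,55,0.25
5,5,60,0.28
5,5,65,0.30
5,5,70,0.33
5,5,75,0.35
5,5,80,0.37
5,5,85,0.39
5,8,20,-0.09
5,8,25,-0.05
5,8,30,-0.02
5,8,35,0.02
5,8,40,0.05
5,8,45,0.07
5,8,50,0.10
5,8,55,0.13
5,8,60,0.15
5,8,65,0.18
5,8,70,0.20
5,8,75,0.22
5,8,80,0.24
5,8,85,0.26
5,13,20,-0.22
5,13,25,-0.18
5,13,30,-0.15
5,13,35,-0.12
5,13,40,-0.09
5,13,45,-0.06
5,13,50,-0.03
5,13,55,-0.00
5,13,60,0.02
5,13,65,0.04
5,13,70,0.07
5,13,75,0.09
5,13,80,0.11
5,13,85,0.13
5,16,25,-0.24
5,16,30,-0.21
5,16,35,-0.17
5,16,40,-0.14
5,16,45,-0.11
5,16,50,-0.09
5,16,55,-0.06
5,16,60,-0.04
5,16,65,-0.01
5,16,70,0.01
5,16,75,0.03
5,16,80,0.05
5,16,85,0.07
5,18,25,-0.27
5,18,30,-0.24
5,18,35,-0.20
5,18,40,-0.17
5,18,45,-0.15
5,18,50,-0.12
5,18,55,-0.09
5,18,60,-0.07
5,18,65,-0.04
5,18,70,-0.02
5,18,75,0.00
5,18,80,0.02
5,18,85,0.04
5,21,30,-0.28
5,21,35,-0.25
5,21,40,-0.22
5,21,45,-0.19
5,21,50,-0.16
5,21,55,-0.13
5,21,60,-0.11
5,21,65,-0.09
5,21,70,-0.06
5,21,75,-0.04
5,21,80,-0.02
5,21,85,0.00
6,5,20,-0.05
6,5,25,-0.02
6,5,30,0.02
6,5,35,0.05
6,5,40,0.08
6,5,45,0.11
6,5,50,0.14
6,5,55,0.17
6,5,60,0.19
6,5,65,0.21
6,5,70,0.24
6,5,75,0.26
6,5,80,0.28
6,5,85,0.30
6,8,20,-0.18
6,8,25,-0.14
6,8,30,-0.11
6,8,35,-0.07
6,8,40,-0.04
6,8,45,-0.01
6,8,50,0.01
6,8,55,0.04
6,8,60,0.06
6,8,65,0.09
6,8,70,0.11
6,8,75,0.13
6,8,80,0.15
6,8,85,0.17
6,13,20,-0.31
6,13,25,-0.27
6,13,30,-0.24
6,13,35,-0.21
6,13,40,-0.18
6,13,45,-0.15
6,13,50,-0.12
6,13,55,-0.09
6,13,60,-0.07
6,13,65,-0.05
6,13,70,-0.02
6,13,75,-0.00
6,13,80,0.02
6,13,85,0.04
6,16,25,-0.33
6,16,30,-0.29
6,16,35,-0.26
6,16,40,-0.23
6,16,45,-0.20
6,16,50,-0.18
6,16,55,-0.15
6,16,60,-0.13
6,16,65,-0.10
6,16,70,-0.08
6,16,75,-0.06
6,16,80,-0.04
6,16,85,-0.02
6,18,25,-0.36
6,18,30,-0.33
6,18,35,-0.29
6,18,40,-0.26
6,18,45,-0.23
6,18,50,-0.21
6,18,55,-0.18
6,18,60,-0.16
6,18,65,-0.13
6,18,70,-0.11
6,18,75,-0.09
6,18,80,-0.07
6,18,85,-0.05
6,21,30,-0.37
6,21,35,-0.34
6,21,40,-0.31
6,21,45,-0.28
6,21,50,-0.25
6,21,55,-0.22
6,21,60,-0.20
6,21,65,-0.18
6,21,70,-0.15
6,21,75,-0.13
6,21,80,-0.11
6,21,85,-0.09
7,5,20,-0.13
7,5,25,-0.09
7,5,30,-0.06
7,5,35,-0.02
7,5,40,0.01
7,5,45,0.04
7,5,50,0.06
7,5,55,0.09
7,5,60,0.11
7,5,65,0.14
7,5,70,0.16
7,5,75,0.18
7,5,80,0.20
7,5,85,0.22
7,8,20,-0.26
7,8,25,-0.22
7,8,30,-0.18
7,8,35,-0.15
7,8,40,-0.12
7,8,45,-0.09
7,8,50,-0.06
7,8,55,-0.04
7,8,60,-0.01
7,8,65,0.01
7,8,70,0.03
7,8,75,0.06
7,8,80,0.08
7,8,85,0.10
7,13,20,-0.39
7,13,25,-0.35
7,13,30,-0.31
7,13,35,-0.28
7,13,40,-0.25
7,13,45,-0.22
7,13,50,-0.20
7,13,55,-0.17
7,13,60,-0.14
7,13,65,-0.12
7,13,70,-0.10
7,13,75,-0.08
7,13,80,-0.06
7,13,85,-0.03
7,16,25,-0.41
7,16,30,-0.37
7,16,35,-0.34
7,16,40,-0.31
7,16,45,-0.28
7,16,50,-0.25
7,16,55,-0.23
7,16,60,-0.20
7,16,65,-0.18
7,16,70,-0.15
7,16,75,-0.13
7,16,80,-0.11
7,16,85,-0.09
7,18,25,-0.44
7,18,30,-0.40
7,18,35,-0.37
7,18,40,-0.34
7,18,45,-0.31
7,18,50,-0.28
7,18,55,-0.26
7,18,60,-0.23
7,18,65,-0.21
7,18,70,-0.19
7,18,75,-0.16
7,18,80,-0.14
7,18,85,-0.12
7,21,30,-0.44
7,21,35,-0.41
7,21,40,-0.38
7,21,45,-0.35
7,21,50,-0.33
7,21,55,-0.30
7,21,60,-0.27
7,21,65,-0.25
7,21,70,-0.23
7,21,75,-0.21
7,21,80,-0.19
7,21,85,-0.16
8,5,20,-0.20
8,5,30,-0.12
8,5,35,-0.09
8,5,40,-0.06
8,5,45,-0.03
8,5,50,-0.00
8,5,55,0.02
8,5,60,0.05
8,5,65,0.07
8,5,70,0.10
8,5,75,0.12
8,5,80,0.14
8,5,85,0.16
8,8,20,-0.32
8,8,25,-0.28
8,8,30,-0.25
8,8,35,-0.22
8,8,40,-0.18
8,8,45,-0.16
8,8,50,-0.13
8,8,55,-0.10
8,8,60,-0.08
8,8,65,-0.06
8,8,70,-0.03
8,8,75,-0.01
8,8,80,0.01
8,8,85,0.03
8,13,20,-0.45
8,13,25,-0.42
8,13,30,-0.38
8,13,35,-0.35
8,13,40,-0.32
8,13,45,-0.29
8,13,50,-0.26
8,13,55,-0.23
8,13,60,-0.21
8,13,65,-0.19
8,13,70,-0.16
8,13,75,-0.14
8,13,80,-0.12
8,13,85,-0.10
8,16,25,-0.47
8,16,30,-0.44
8,16,35,-0.40
8,16,40,-0.37
8,16,45,-0.34
8,16,50,-0.32
8,16,55,-0.29
8,16,60,-0.27
8,16,65,-0.24
8,16,70,-0.22
8,16,75,-0.20
8,16,80,-0.18
8,16,85,-0.16
8,18,25,-0.50
8,18,30,-0.47
8,18,35,-0.44
8,18,40,-0.40
8,18,45,-0.38
8,18,50,-0.35
8,18,55,-0.32
8,18,60,-0.30
8,18,65,-0.27
8,18,70,-0.25
8,18,75,-0.23
8,18,80,-0.21
8,18,85,-0.19
8,21,30,-0.51
8,21,35,-0.48
8,21,40,-0.45
8,21,45,-0.42
8,21,50,-0.39
8,21,55,-0.36
8,21,60,-0.34
8,21,65,-0.32
8,21,70,-0.29
8,21,75,-0.27
8,21,80,-0.25
8,21,85,-0.23
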