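span,education,age,correction
2,5,20,8.72
2,5,25,9.16
2,5,30,9.56
2,5,35,9.93
2,5,40,10.27
2,5,45,10.60
2,5,50,10.90
2,5,55,11.19
2,5,60,11.47
2,5,65,11.74
2,5,70,11.99
2,5,75,12.24
2,5,80,12.48
2,5,85,12.71
2,8,20,7.03
2,8,25,7.47
2,8,30,7.87
2,8,35,8.24
2,8,40,8.58
2,8,45,8.91
2,8,50,9.21
2,8,55,9.50
2,8,60,9.78
2,8,65,10.05
2,8,70,10.30
2,8,75,10.55
2,8,80,10.79
2,8,85,11.02
2,13,20,4.81
2,13,25,5.25
2,13,30,5.66
2,13,35,6.02
2,13,40,6.37
2,13,45,6.69
2,13,50,7.00
2,13,55,7.29
2,13,60,7.56
2,13,65,7.83
2,13,70,8.09
2,13,75,8.33
2,13,80,8.57
2,13,85,8.80
2,16,25,4.13
2,16,30,4.53
2,16,35,4.90
2,16,40,5.24
2,16,45,5.57
2,16,50,5.87
2,16,55,6.16
2,16,60,6.44
2,16,65,6.70
2,16,70,6.96
2,16,75,7.21
2,16,80,7.45
2,16,85,7.68
2,18,25,3.44
2,18,30,3.84
2,18,35,4.21
2,18,40,4.55
2,18,45,4.87
2,18,50,5.18
2,18,55,5.47
2,18,60,5.75
2,18,65,6.01
2,18,70,6.27
2,18,75,6.52
2,18,80,6.75
2,18,85,6.99
2,21,30,2.87
2,21,35,3.24
2,21,40,3.58
2,21,45,3.90
2,21,50,4.21
2,21,55,4.50
2,21,60,4.78
2,21,65,5.04
2,21,70,5.30
2,21,75,5.55
2,21,80,5.79
2,21,85,6.02
3,5,20,5.90
3,5,25,6.35
3,5,30,6.75
3,5,35,7.12
3,5,40,7.46
3,5,45,7.78
3,5,50,8.09
3,5,55,8.38
3,5,60,8.66
3,5,65,8.92
3,5,70,9.18
3,5,75,9.42
3,5,80,9.66
3,5,85,9.89
3,8,20,4.21
3,8,25,4.66
3,8,30,5.06
3,8,35,5.43
3,8,40,5.77
3,8,45,6.09
3,8,50,6.40
3,8,55,6.69
3,8,60,6.97
3,8,65,7.23
3,8,70,7.49
3,8,75,7.73
3,8,80,7.97
3,8,85,8.20
3,13,20,2.00
3,13,25,2.44
3,13,30,2.84
3,13,35,3.21
3,13,40,3.55
3,13,45,3.88
3,13,50,4.18
3,13,55,4.47
3,13,60,4.75
3,13,65,5.02
3,13,70,5.27
3,13,75,5.52
3,13,80,5.76
3,13,85,5.99
3,16,25,1.31
3,16,30,1.72
3,16,35,2.09
3,16,40,2.43
3,16,45,2.75
3,16,50,3.06
3,16,55,3.35
3,16,60,3.62
3,16,65,3.89
3,16,70,4.15
3,16,75,4.39
3,16,80,4.63
3,16,85,4.86
3,18,25,0.62
3,18,30,1.02
3,18,35,1.39
3,18,40,1.74
3,18,45,2.06
3,18,50,2.36
3,18,55,2.65
3,18,60,2.93
3,18,65,3.20
3,18,70,3.45
3,18,75,3.70
3,18,80,3.94
3,18,85,4.17
3,21,30,0.05
3,21,35,0.42
3,21,40,0.77
3,21,45,1.09
3,21,50,1.40
3,21,55,1.69
3,21,60,1.96
3,21,65,2.23
3,21,70,2.48
3,21,75,2.73
3,21,80,2.97
3,21,85,3.20
4,5,20,3.53
4,5,25,3.97
4,5,30,4.37
4,5,35,4.74
4,5,40,5.09
4,5,45,5.41
4,5,50,5.71
4,5,55,6.01
4,5,60,6.28
4,5,65,6.55
4,5,70,6.80
4,5,75,7.05
4,5,80,7.29
4,5,85,7.52
4,8,20,1.84
4,8,25,2.28
4,8,30,2.68
4,8,35,3.05
4,8,40,3.40
4,8,45,3.72
4,8,50,4.03
4,8,55,4.32
4,8,60,4.59
4,8,65,4.86
4,8,70,5.11
4,8,75,5.36
4,8,80,5.60
4,8,85,5.83
4,13,20,-0.38
4,13,25,0.07
4,13,30,0.47
4,13,35,0.84
4,13,40,1.18
4,13,45,1.50
4,13,50,1.81
4,13,55,2.10
4,13,60,2.38
4,13,65,2.64
4,13,70,2.90
4,13,75,3.15
4,13,80,3.38
4,13,85,3.62
4,16,25,-1.06
4,16,30,-0.66
4,16,35,-0.29
4,16,40,0.06
4,16,45,0.38
4,16,50,0.68
4,16,55,0.97
4,16,60,1.25
4,16,65,1.52
4,16,70,1.77
4,16,75,2.02
4,16,80,2.26
4,16,85,2.49
4,18,25,-1.75
4,18,30,-1.35
4,18,35,-0.98
4,18,40,-0.64
4,18,45,-0.31
4,18,50,-0.01
4,18,55,0.28
4,18,60,0.56
4,18,65,0.83
4,18,70,1.08
4,18,75,1.33
4,18,80,1.57
4,18,85,1.80
4,21,30,-2.32
4,21,35,-1.95
4,21,40,-1.61
4,21,45,-1.28
4,21,50,-0.98
4,21,55,-0.69
4,21,60,-0.41
4,21,65,-0.14
4,21,70,0.11
4,21,75,0.36
4,21,80,0.60
4,21,85,0.83
5,5,20,1.44
5,5,25,1.88
5,5,30,2.28
5,5,35,2.65
5,5,40,3.00
5,5,45,3.32
5,5,50,3.62
5,5,55,3.91
5,5,60,4.19
5,5,65,4.46
5,5,70,4.71
5,5,75,4.96
5,5,80,5.20
5,5,85,5.43
5,8,20,-0.25
5,8,25,0.19
5,8,30,0.59
5,8,35,0.96
5,8,40,1.31
5,8,45,1.63
5,8,50,1.93
5,8,55,2.23
5,8,60,2.50
5,8,65,2.77
5,8,70,3.02
5,8,75,3.27
5,8,80,3.51
5,8,85,3.74
5,13,20,-2.47
5,13,25,-2.02
5,13,30,-1.62
5,13,35,-1.25
5,13,40,-0.91
5,13,45,-0.59
5,13,50,-0.28
5,13,55,0.01
5,13,60,0.29
5,13,65,0.55
5,13,70,0.81
5,13,75,1.06
5,13,80,1.29
5,13,85,1.53
5,16,25,-3.15
5,16,30,-2.75
5,16,35,-2.38
5,16,40,-2.03
5,16,45,-1.71
5,16,50,-1.41
5,16,55,-1.12
5,16,60,-0.84
5,16,65,-0.57
5,16,70,-0.32
5,16,75,-0.07
5,16,80,0.17
5,16,85,0.40
5,18,25,-3.84
5,18,30,-3.44
5,18,35,-3.07
5,18,40,-2.73
5,18,45,-2.40
5,18,50,-2.10
5,18,55,-1.81
5,18,60,-1.53
5,18,65,-1.26
5,18,70,-1.01
5,18,75,-0.76
5,18,80,-0.52
5,18,85,-0.29
5,21,30,-4.41
5,21,35,-4.04
5,21,40,-3.70
5,21,45,-3.37
5,21,50,-3.07
5,21,55,-2.78
5,21,60,-2.50
5,21,65,-2.23
5,21,70,-1.98
5,21,75,-1.73
5,21,80,-1.49
5,21,85,-1.26
6,5,20,-0.45
6,5,25,-0.01
6,5,30,0.39
6,5,35,0.76
6,5,40,1.11
6,5,45,1.43
6,5,50,1.73
6,5,55,2.02
6,5,60,2.30
6,5,65,2.57
6,5,70,2.82
6,5,75,3.07
6,5,80,3.31
6,5,85,3.54
6,8,20,-2.14
6,8,25,-1.70
6,8,30,-1.30
6,8,35,-0.93
6,8,40,-0.58
6,8,45,-0.26
6,8,50,0.05
6,8,55,0.34
6,8,60,0.61
6,8,65,0.88
6,8,70,1.13
6,8,75,1.38
6,8,80,1.62
6,8,85,1.85
6,13,20,-4.36
6,13,25,-3.91
6,13,30,-3.51
6,13,35,-3.14
6,13,40,-2.80
6,13,45,-2.48
6,13,50,-2.17
6,13,55,-1.88
6,13,60,-1.60
6,13,65,-1.34
6,13,70,-1.08
6,13,75,-0.83
6,13,80,-0.60
6,13,85,-0.36
6,16,25,-5.04
6,16,30,-4.64
6,16,35,-4.27
6,16,40,-3.92
6,16,45,-3.60
6,16,50,-3.30
6,16,55,-3.01
6,16,60,-2.73
6,16,65,-2.46
6,16,70,-2.21
6,16,75,-1.96
6,16,80,-1.72
6,16,85,-1.49
6,18,25,-5.73
6,18,30,-5.33
6,18,35,-4.96
6,18,40,-4.62
6,18,45,-4.29
6,18,50,-3.99
6,18,55,-3.70
6,18,60,-3.42
6,18,65,-3.15
6,18,70,-2.90
6,18,75,-2.65
6,18,80,-2.41
6,18,85,-2.18
6,21,30,-6.30
6,21,35,-5.93
6,21,40,-5.59
6,21,45,-5.26
6,21,50,-4.96
6,21,55,-4.67
6,21,60,-4.39
6,21,65,-4.12
6,21,70,-3.87
6,21,75,-3.62
6,21,80,-3.38
6,21,85,-3.15
7,5,20,-2.19
7,5,25,-1.75
7,5,30,-1.34
7,5,35,-0.97
7,5,40,-0.62
7,5,45,-0.31
7,5,50,-0.00
7,5,55,0.29
7,5,60,0.56
7,5,65,0.83
7,5,70,1.09
7,5,75,1.33
7,5,80,1.57
7,5,85,1.80
7,8,20,-3.88
7,8,25,-3.43
7,8,30,-3.03
7,8,35,-2.66
7,8,40,-2.32
7,8,45,-2.00
7,8,50,-1.69
7,8,55,-1.40
7,8,60,-1.13
7,8,65,-0.86
7,8,70,-0.60
7,8,75,-0.36
7,8,80,-0.12
7,8,85,0.11
7,13,20,-6.09
7,13,25,-5.65
7,13,30,-5.25
7,13,35,-4.88
7,13,40,-4.54
7,13,45,-4.21
7,13,50,-3.91
7,13,55,-3.62
7,13,60,-3.34
7,13,65,-3.08
7,13,70,-2.82
7,13,75,-2.57
7,13,80,-2.33
7,13,85,-2.10
7,16,25,-6.78
7,16,30,-6.37
7,16,35,-6.01
7,16,40,-5.66
7,16,45,-5.34
7,16,50,-5.03
7,16,55,-4.74
7,16,60,-4.47
7,16,65,-4.20
7,16,70,-3.94
7,16,75,-3.70
7,16,80,-3.46
7,16,85,-3.23
7,18,25,-7.47
7,18,30,-7.07
7,18,35,-6.70
7,18,40,-6.35
7,18,45,-6.03
7,18,50,-5.73
7,18,55,-5.44
7,18,60,-5.16
7,18,65,-4.89
7,18,70,-4.64
7,18,75,-4.39
7,18,80,-4.15
7,18,85,-3.92
7,21,30,-8.04
7,21,35,-7.67
7,21,40,-7.32
7,21,45,-7.00
7,21,50,-6.70
7,21,55,-6.41
7,21,60,-6.13
7,21,65,-5.86
7,21,70,-5.61
7,21,75,-5.36
7,21,80,-5.12
7,21,85,-4.89
8,5,20,-3.81
8,5,25,-3.36
8,5,30,-2.96
8,5,35,-2.59
8,5,40,-2.25
8,5,45,-1.93
8,5,50,-1.62
8,5,55,-1.33
8,5,60,-1.05
8,5,65,-0.79
8,5,70,-0.53
8,5,75,-0.28
8,5,80,-0.05
8,5,85,0.19
8,8,20,-5.50
8,8,25,-5.05
8,8,30,-4.65
8,8,35,-4.28
8,8,40,-3.94
8,8,45,-3.62
8,8,50,-3.31
8,8,55,-3.02
8,8,60,-2.74
8,8,65,-2.48
8,8,70,-2.22
8,8,75,-1.97
8,8,80,-1.74
8,8,85,-1.50
8,13,20,-7.71
8,13,25,-7.27
8,13,30,-6.87
8,13,35,-6.50
8,13,40,-6.15
8,13,45,-5.83
8,13,50,-5.53
8,13,55,-5.24
8,13,60,-4.96
8,13,65,-4.69
8,13,70,-4.44
8,13,75,-4.19
8,13,80,-3.95
8,13,85,-3.72
8,16,25,-8.39
8,16,30,-7.99
8,16,35,-7.62
8,16,40,-7.28
8,16,45,-6.96
8,16,50,-6.65
8,16,55,-6.36
8,16,60,-6.08
8,16,65,-5.82
8,16,70,-5.56
8,16,75,-5.32
8,16,80,-5.08
8,16,85,-4.84
8,18,25,-9.09
8,18,30,-8.68
8,18,35,-8.32
8,18,40,-7.97
8,18,45,-7.65
8,18,50,-7.34
8,18,55,-7.05
8,18,60,-6.78
8,18,65,-6.51
8,18,70,-6.25
8,18,75,-6.01
8,18,80,-5.77
8,18,85,-5.54
8,21,30,-9.65
8,21,35,-9.28
8,21,40,-8.94
8,21,45,-8.62
8,21,50,-8.31
8,21,55,-8.02
8,21,60,-7.75
8,21,65,-7.48
8,21,70,-7.22
8,21,75,-6.98
8,21,80,-6.74
8,21,85,-6.51
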