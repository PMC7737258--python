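pelvic_tilt_deg,actual_va_deg,measured_va_deg
20,0,29.60
20,5,34.41
20,10,39.44
20,15,44.59
20,20,49.34
20,25,54.06
20,30,59.82
20,35,64.84
20,40,70.05
25,0,26.03
25,5,30.62
25,10,35.71
25,15,40.65
25,20,46.87
25,25,51.18
25,30,56.69
25,35,61.68
25,40,66.16
30,0,22.57
30,5,27.63
30,10,32.17
30,15,37.99
30,20,43.02
30,25,48.65
30,30,52.39
30,35,57.50
30,40,63.23
35,0,18.70
35,5,23.90
35,10,29.60
35,15,34.20
35,20,39.42
35,25,44.09
35,30,49.58
35,35,54.92
35,40,59.33
40,0,15.30
40,5,20.49
40,10,25.53
40,15,31.32
40,20,35.86
40,25,40.44
40,30,45.00
40,35,50.54
40,40,55.93
45,0,11.39
45,5,16.54
45,10,21.55
45,15,26.41
45,20,32.22
45,25,36.80
45,30,41.22
45,35,47.02
45,40,50.26
50,0,8.68
50,5,12.83
50,10,17.48
50,15,21.84
50,20,27.24
50,25,31.73
50,30,37.69
50,35,42.36
50,40,48.03
55,0,6.66
55,5,5.48
55,10,12.98
55,15,18.72
55,20,23.28
55,25,28.39
55,30,33.58
55,35,38.12
55,40,43.66
60,0,0.66
60,5,4.11
60,10,7.34
60,15,13.45
60,20,18.76
60,25,24.79
60,30,30.86
60,35,35.59
60,40,39.83
65,0,-2.76
65,5,1.32
65,10,3.84
65,15,11.21
65,20,15.51
65,25,20.37
65,30,26.16
65,35,31.80
65,40,36.12
70,0,-9.40
70,5,-1.83
70,10,0.82
70,15,3.59
70,20,11.45
70,25,17.47
70,30,23.34
70,35,27.89
70,40,32.87
75,0,-12.75
75,5,-6.13
75,10,2.31
75,15,2.64
75,20,6.78
75,25,13.46
75,30,19.55
75,35,24.85
75,40,29.52
80,0,-16.70
80,5,-11.63
80,10,-4.16
80,15,0.80
80,20,4.05
80,25,9.41
80,30,14.44
80,35,20.55
80,40,25.81
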