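group,mouse_id,day,score
healthy,1,0,65.89
healthy,2,0,14.32
healthy,3,0,34.97
healthy,4,0,61.81
healthy,5,0,25.33
healthy,6,0,70.4
healthy,7,0,46.29
healthy,8,0,72.34
healthy,9,0,26.59
healthy,10,0,86.88
healthy,11,0,16.88
healthy,12,0,23.8
healthy,13,0,88.29
healthy,14,0,46.58
healthy,15,0,93.63
disease1,1,0,82.12
disease1,1,64,1.05
disease1,1,69,1.26
disease1,2,0,111.74
disease1,2,64,1.57
disease1,2,69,20.78
disease1,2,74,1.65
disease1,3,0,214.96
disease1,3,64,1.4
disease1,3,69,10.82
disease1,3,74,6.71
disease1,4,0,199.62
disease1,4,64,4.41
disease1,4,69,4.83
disease1,4,74,1.96
disease1,5,0,66.81
disease1,5,64,7.55
disease1,5,69,0.74
disease1,5,74,2.04
disease1,6,0,177.22
disease1,6,64,5.16
disease1,6,69,1.65
disease1,6,74,2.37
disease1,7,0,72.02
disease1,7,64,10.33
disease1,7,69,1.42
disease1,7,74,0.93
disease1,8,0,111.65
disease1,8,64,72.55
disease1,8,69,2.75
disease1,8,74,2.83
disease1,9,0,213.76
disease1,9,64,2.53
disease1,9,69,9.85
disease1,9,74,0.87
disease1,10,0,169.2
disease1,10,64,3.93
disease1,10,69,1.18
disease1,10,74,2.26
disease1,11,0,118.98
disease1,11,64,2.35
disease1,12,0,24.07
disease1,12,64,13.27
disease1,12,69,2.05
disease1,12,74,2.11
disease1,13,0,74.3
disease1,13,64,7.85
disease1,13,69,0.68
disease1,13,74,3.62
disease1,14,0,193.03
disease1,14,64,0.83
disease1,14,69,13.17
disease1,14,74,2.38
disease1,15,0,394.17
disease1,15,64,1.86
disease1,15,69,0.59
disease1,15,74,0.62
disease1,16,0,90.85
disease1,16,64,62.97
disease1,16,69,11.41
disease1,16,74,2.86
disease1,17,0,57.7
disease1,17,64,0.6
disease1,17,69,12.34
disease2,1,0,31.93
disease2,1,55,9.5
disease2,1,77,18.89
disease2,1,93,19.77
disease2,2,0,57.44
disease2,2,55,31.09
disease2,3,0,163.22
disease2,3,55,1.41
disease2,3,77,1.6
disease2,3,93,3.29
disease2,4,0,38.51
disease2,4,55,3.59
disease2,4,77,7.05
disease2,4,93,13.59
disease2,5,0,52.02
disease2,5,55,5.98
disease2,5,77,20.52
disease2,5,93,28.64
disease2,6,0,127.93
disease2,6,55,9.52
disease2,6,77,15.55
disease2,6,93,17.99
disease2,7,0,97.35
disease2,7,55,16.15
disease2,7,77,14.07
disease2,7,93,4.62
disease2,8,0,59.87
disease2,8,55,19.28
disease2,8,77,5.45
disease2,9,0,34.51
disease2,9,55,16.19
disease2,9,77,27.19
disease2,9,93,74.25
disease2,10,0,186.73
disease2,10,55,4.13
disease2,10,77,3.3
disease2,10,93,16.2
disease2,11,0,31.97
disease2,11,55,15.13
disease2,11,77,31.33
disease2,11,93,15.4
disease2,12,0,213.79
disease2,12,55,85.38
disease2,12,77,16.48
disease2,12,93,32.83
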