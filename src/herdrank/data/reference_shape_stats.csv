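cow_id,skewness,kurtosis,peak_x,peak_y
Cow01,1.33,5.09,6.12,24.22
Cow02,0.31,2.22,8.73,19.67
Cow03,0.25,2.97,7.55,23.33
Cow04,-0.29,2.44,8.23,17.25
Cow05,0.09,2.07,6.50,16.07
Cow06,1.07,5.09,6.86,24.81
Cow07,0.67,2.56,6.84,20.35
Cow08,0.57,2.77,8.88,21.86
Cow09,-0.33,2.33,10.30,17.86
Cow10,0.27,2.46,8.44,19.50
Cow11,-0.21,2.16,10.30,19.50
Cow12,0.68,3.92,8.66,23.13
Cow13,-0.05,2.95,8.51,18.35
Cow14,0.58,2.60,7.55,17.33
Cow15,0.99,4.53,8.13,18.78
Cow16,-0.12,1.91,10.71,16.34
Cow17,0.30,2.92,8.55,19.18
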