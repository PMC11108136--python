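age,mms_female,mms_male,mms_total,catalonia_female,catalonia_male,catalonia_total,spain_female,spain_male,spain_total
0,85.82,80.58,83.20,86.16,80.71,83.5,85.73,80.37,83.09
10,75.86,70.60,73.23,76.41,70.97,73.75,75.99,70.68,73.37
20,65.99,60.74,63.36,66.47,61.08,63.84,66.06,60.77,63.46
30,56.09,50.91,53.50,56.57,51.27,53.99,56.17,50.99,53.62
40,46.23,41.05,43.64,46.72,41.54,44.2,46.33,41.26,43.84
50,36.49,31.52,34.02,37.05,32.03,34.62,36.69,31.82,34.31
60,26.99,22.86,24.97,27.79,23.25,25.62,27.44,23.13,25.37
70,17.82,15.20,16.60,18.87,15.45,17.31,18.59,15.37,17.11
80,9.86,8.98,9.49,10.71,8.7,9.89,10.56,8.72,9.8
90,6.45,6.42,6.44,4.91,4.14,4.67,4.86,4.24,4.67
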