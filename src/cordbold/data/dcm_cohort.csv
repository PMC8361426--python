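case_id,age,sex,site_of_impairment,duration_months,mjoa_upper_motor,mjoa_lower_motor,mjoa_upper_sensory,mjoa_bladder,mjoa_total
1,70,M,C3-4,7,2,2,1,1,6
2,51,M,C6-7,4,3,4,1,1,9
3,68,M,C5-6,15,3,4,1,3,11
4,57,F,C5-6,30,2,4,1,1,8
5,81,M,C5-6,12,2,4,1,3,10
6,77,M,C4-5,4,3,4,1,2,10
7,74,M,C4-5,24,4,6,1,3,14
8,60,M,C5-6,36,4,4,1,3,12
9,52,F,C3-4,12,1,6,0,1,8
10,82,F,C3-4,12,4,6,2,3,15
11,52,M,C5-6,4,4,3,1,2,10
12,70,M,C3-4,22,3,4,1,2,10
13,72,M,C3-4,24,2,4,1,2,9
14,77,M,C3-4,5,2,3,1,2,8
15,51,F,C4-5,11,4,4,1,2,11
16,34,F,C4-5,16,3,5,1,2,11
17,84,M,C3-4,7,2,3,1,2,8
18,79,F,C4-5,6,2,3,1,2,8
19,45,M,C3-4,5,3,4,1,2,10
20,72,F,C3-4,24,2,3,1,3,9
21,67,F,C4-5,3,2,4,1,2,9
22,56,F,C3-4,7,4,4,2,3,13
23,73,M,C3-4,3,3,3,1,2,9
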