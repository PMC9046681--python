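total_score,theta,percent
0,-4.0889,0
1,-3.9961,1
2,-3.9011,3
3,-3.8041,5
4,-3.7049,6
5,-3.6035,8
6,-3.5001,9
7,-3.3945,11
8,-3.2867,13
9,-3.1769,15
10,-3.0649,16
11,-2.9507,18
12,-2.8345,20
13,-2.7161,22
14,-2.5956,24
15,-2.4729,26
16,-2.3481,28
17,-2.2212,30
18,-2.0922,32
19,-1.961,34
20,-1.8277,36
21,-1.6922,38
22,-1.5546,40
23,-1.4149,43
24,-1.2731,45
25,-1.1291,47
26,-0.983,49
27,-0.8348,52
28,-0.6844,54
29,-0.5319,57
30,-0.3773,59
31,-0.2205,62
32,-0.0616,64
33,0.0994,67
34,0.2625,69
35,0.4278,72
36,0.5952,75
37,0.7648,77
38,0.9365,80
39,1.1103,83
40,1.2862,85
41,1.4643,88
42,1.6445,91
43,1.8269,94
44,2.0113,97
45,2.198,100
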