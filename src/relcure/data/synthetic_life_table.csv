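age,sex,year,value
40,male,2010,0.0015979470333103392
41,male,2010,0.0017013454087186014
42,male,2010,0.0018144812520672188
43,male,2010,0.001938271582424577
44,male,2010,0.0020737197784729718
45,male,2010,0.0022219237113633855
46,male,2010,0.0023840846434760496
47,male,2010,0.0025615169652153926
48,male,2010,0.0027556588487606935
49,male,2010,0.0029680839051260503
50,male,2010,0.0032005139390156546
51,male,2010,0.0034548329048583893
52,male,2010,0.003733102177142014
53,male,2010,0.004037577258820119
54,male,2010,0.004370726063221344
55,male,2010,0.004735248917644305
56,male,2010,0.005134100450776726
57,male,2010,0.005570513541346616
58,male,2010,0.006048025522120502
59,male,2010,0.006570506851644425
60,male,2010,0.007142192486125609
61,male,2010,0.007767716205738625
62,male,2010,0.008452148173586808
63,male,2010,0.009201036031752041
64,male,2010,0.010020449867535515
65,male,2010,0.010917031414362035
66,male,2010,0.011898047886144252
67,male,2010,0.012971450881459571
68,male,2010,0.014145940834985752
69,male,2010,0.015431037538604213
70,male,2010,0.01683715730377787
71,male,2010,0.018375697390640492
72,male,2010,0.02005912838813516
73,male,2010,0.02190109529398603
74,male,2010,0.02391652811380413
75,male,2010,0.02612176287578455
76,male,2010,0.028534674041876304
77,male,2010,0.031174819388679057
78,male,2010,0.0340635985323946
79,male,2010,0.037224426382752106
80,male,2010,0.04068292293183251
81,male,2010,0.04446712091611954
82,male,2010,0.04860769303497546
83,male,2010,0.0531382005672544
84,male,2010,0.05809536540120678
85,male,2010,0.06351936768260527
86,male,2010,0.0694541714936699
87,male,2010,0.07594788120257255
88,male,2010,0.08305313137190061
89,male,2010,0.09082751338647148
90,male,2010,0.0993340422585152
91,male,2010,0.10864166739390135
92,male,2010,0.1188258314594091
93,male,2010,0.12996908188092238
94,male,2010,0.14216173992902945
95,male,2010,0.15550263281527957
96,male,2010,0.17009989473308054
97,male,2010,0.18607184333604745
98,male,2010,0.2035479387580752
99,male,2010,0.22266983294843634
100,male,2010,0.24359251782726155
101,male,2010,0.26648558156773994
102,male,2010,0.2915345831877956
103,male,2010,0.3189425565929507
104,male,2010,0.34893165626134764
105,male,2010,0.3817449579099801
106,male,2010,0.41764842873737545
107,male,2010,0.4569330832124717
108,male,2010,0.4999173418833668
109,male,2010,0.5469496123251939
40,female,2010,0.0015979470333103392
41,female,2010,0.0017013454087186014
42,female,2010,0.0018144812520672188
43,female,2010,0.001938271582424577
44,female,2010,0.0020737197784729718
45,female,2010,0.0022219237113633855
46,female,2010,0.0023840846434760496
47,female,2010,0.0025615169652153926
48,female,2010,0.0027556588487606935
49,female,2010,0.0029680839051260503
50,female,2010,0.0032005139390156546
51,female,2010,0.0034548329048583893
52,female,2010,0.003733102177142014
53,female,2010,0.004037577258820119
54,female,2010,0.004370726063221344
55,female,2010,0.004735248917644305
56,female,2010,0.005134100450776726
57,female,2010,0.005570513541346616
58,female,2010,0.006048025522120502
59,female,2010,0.006570506851644425
60,female,2010,0.007142192486125609
61,female,2010,0.007767716205738625
62,female,2010,0.008452148173586808
63,female,2010,0.009201036031752041
64,female,2010,0.010020449867535515
65,female,2010,0.010917031414362035
66,female,2010,0.011898047886144252
67,female,2010,0.012971450881459571
68,female,2010,0.014145940834985752
69,female,2010,0.015431037538604213
70,female,2010,0.01683715730377787
71,female,2010,0.018375697390640492
72,female,2010,0.02005912838813516
73,female,2010,0.02190109529398603
74,female,2010,0.02391652811380413
75,female,2010,0.02612176287578455
76,female,2010,0.028534674041876304
77,female,2010,0.031174819388679057
78,female,2010,0.0340635985323946
79,female,2010,0.037224426382752106
80,female,2010,0.04068292293183251
81,female,2010,0.04446712091611954
82,female,2010,0.04860769303497546
83,female,2010,0.0531382005672544
84,female,2010,0.05809536540120678
85,female,2010,0.06351936768260527
86,female,2010,0.0694541714936699
87,female,2010,0.07594788120257255
88,female,2010,0.08305313137190061
89,female,2010,0.09082751338647148
90,female,2010,0.0993340422585152
91,female,2010,0.10864166739390135
92,female,2010,0.1188258314594091
93,female,2010,0.12996908188092238
94,female,2010,0.14216173992902945
95,female,2010,0.15550263281527957
96,female,2010,0.17009989473308054
97,female,2010,0.18607184333604745
98,female,2010,0.2035479387580752
99,female,2010,0.22266983294843634
100,female,2010,0.24359251782726155
101,female,2010,0.26648558156773994
102,female,2010,0.2915345831877956
103,female,2010,0.3189425565929507
104,female,2010,0.34893165626134764
105,female,2010,0.3817449579099801
106,female,2010,0.41764842873737545
107,female,2010,0.4569330832124717
108,female,2010,0.4999173418833668
109,female,2010,0.5469496123251939
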