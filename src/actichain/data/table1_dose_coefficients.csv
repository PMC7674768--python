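patient,kidneys,liver,parotid,submandibular,red_marrow,whole_body
1,0.67,0.23,1.28,1.52,,0.11
2,0.54,0.17,2.43,1.98,0.08,0.05
3,1.81,0.08,0.64,0.79,0.08,0.04
4,0.15,0.02,0.70,1.05,0.03,0.02
5,0.86,0.23,1.16,0.87,0.08,0.04
6,0.42,0.06,0.86,1.09,0.14,0.09
7,0.57,0.12,0.57,1.15,0.07,0.02
8,0.70,0.14,0.52,0.96,0.03,0.03
9,0.45,0.09,0.49,1.30,0.05,0.04
10,0.54,0.08,1.11,0.83,0.05,0.04
11,0.67,0.09,1.39,0.68,,0.03
12,1.06,0.24,1.83,1.89,,0.09
13,0.73,0.11,0.50,0.42,,0.02
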