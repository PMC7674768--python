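patient,parotid,submandibular,salivary
1,56.6,57.8,57.2
2,237.0,203.9,220.4
3,15.4,22.0,18.7
4,42.1,140.5,91.3
5,36.5,15.7,26.1
6,22.9,33.8,28.3
7,27.6,104.7,66.2
8,22.2,55.0,38.6
9,12.4,91.3,51.9
10,49.0,23.4,36.2
11,125.9,34.0,80.0
12,142.2,138.2,140.2
13,19.7,12.1,15.9
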