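experiment,precision,recall,f1,auc
1,81.63,83.33,82.47,0.8302
2,80.39,85.42,82.83,0.8333
3,80.39,85.42,82.83,0.8169
4,86.00,89.58,87.76,0.8754
5,82.35,87.50,84.85,0.8486
6,81.82,75.00,78.26,0.7945
7,81.82,93.75,87.38,0.8652
8,81.48,91.67,86.28,0.8712
9,86.05,77.08,81.32,0.8185
10,85.11,85.11,85.10,0.8703
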