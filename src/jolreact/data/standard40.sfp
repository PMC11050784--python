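F5	-66.698	49.698	17.507
F3	-50.594	53.481	42.486
F1	-26.742	55.369	58.687
FC5	-78.967	19.066	25.015
FC3	-60.190	22.719	55.552
FC1	-31.905	24.364	74.923
F6	67.274	49.360	16.213
F4	51.563	54.019	40.599
F2	28.526	55.674	57.547
FC6	79.015	19.805	24.278
FC4	60.987	23.225	54.463
FC2	32.812	24.939	74.340
Fz	0.300	56.167	63.798
FCz	0.344	25.087	81.213
C5	-78.876	-13.519	28.650
C3	-60.085	-10.693	59.165
C1	-31.595	-8.724	78.426
CP5	-69.558	-40.682	27.047
CP3	-52.581	-38.891	54.292
CP1	-27.746	-36.949	71.344
C6	79.404	-12.156	27.790
C4	61.284	-9.953	58.054
C2	33.154	-8.470	77.808
CP6	70.676	-39.105	26.470
CP4	54.200	-37.947	53.361
CP2	29.890	-36.656	70.625
Cz	0.339	-7.741	84.646
CPz	0.298	-36.525	76.752
P5	-54.149	-61.408	22.845
P3	-40.882	-60.765	43.143
P1	-21.341	-60.045	56.251
PO5	-36.553	-74.987	16.304
PO3	-27.340	-75.518	27.831
P6	54.625	-61.075	22.603
P4	42.373	-59.799	43.054
P2	23.454	-59.140	56.369
PO4	27.582	-75.626	27.294
PO2	14.871	-76.153	34.707
Pz	0.238	-59.551	60.652
POz	0.161	-76.169	37.726
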