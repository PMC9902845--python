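region,MMDM01,MMDM02,MMDM03,MMDN01,MMDN02,MMDN03,MMDN04,MMDN05,MMDN06
liver,1.05,0.62,0.82,1.23,0.71,1.00,0.80,0.71,0.83
kidneys,0.10,0.20,0.16,0.12,0.28,0.13,0.12,0.08,0.13
bladder_content,3.21,3.29,4.34,1.08,2.10,6.72,9.25,7.46,12.48
spleen,0.23,0.19,0.27,0.48,0.18,0.31,0.20,0.25,0.26
red_marrow,4.75,3.11,2.89,2.02,1.83,2.93,1.89,1.54,1.56
heart_content,0.072,0.053,0.061,0.055,0.041,0.067,0.042,0.015,0.035
total,9.41,7.47,8.54,4.99,5.15,11.16,12.30,10.05,15.28
mird_void,0.19,0.20,0.24,0.10,0.15,0.43,0.48,0.43,0.68
excreted,3.02,3.09,4.10,0.99,1.95,6.29,8.77,7.03,11.79
remainder,8.91,10.85,9.78,13.34,13.18,7.17,6.02,8.27,3.05
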