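organ,MMDM01,MMDM02,MMDM03,MMDN01,MMDN02,MMDN03,MMDN04,MMDN05,MMDN06
adrenals,0.029,0.024,0.022,0.027,0.026,0.023,0.018,0.017,0.011
brain,0.020,0.017,0.015,0.020,0.020,0.015,0.012,0.013,0.004
breasts,0.018,,,,,0.014,0.012,,0.004
gallbladder_wall,0.026,0.022,0.021,0.028,0.026,0.021,0.017,0.017,0.009
lower_large_intestine_wall,0.026,0.022,0.020,0.025,0.024,0.021,0.017,0.017,0.009
small_intestine_wall,0.025,0.022,0.020,0.026,0.025,0.019,0.015,0.016,0.008
stomach_wall,0.023,0.021,0.019,0.025,0.024,0.018,0.015,0.015,0.006
upper_large_intestine_wall,0.025,0.021,0.019,0.025,0.024,0.020,0.016,0.016,0.007
heart_wall,0.029,0.026,0.023,0.028,0.026,0.024,0.018,0.016,0.009
kidneys,0.042,0.063,0.052,0.043,0.084,0.048,0.042,0.028,0.044
liver,0.073,0.035,0.044,0.064,0.039,0.068,0.054,0.037,0.055
lungs,0.022,0.019,0.017,0.023,0.022,0.018,0.014,0.014,0.006
muscle,0.021,0.018,0.017,0.022,0.021,0.016,0.013,0.014,0.005
ovaries,0.026,,,,,0.021,0.017,,0.009
pancreas,0.027,0.023,0.022,0.029,0.027,0.022,0.017,0.018,0.009
red_marrow,0.165,0.123,0.113,0.088,0.081,0.121,0.070,0.064,0.112
skeleton,0.158,0.093,0.085,0.080,0.076,0.117,0.074,0.055,0.092
skin,0.017,0.016,0.014,0.019,0.018,0.013,0.011,0.012,0.004
spleen,0.132,0.123,0.124,0.220,0.138,0.170,0.111,0.116,0.141
testes,,0.017,0.016,0.021,0.020,,,0.013,
thymus,0.021,0.019,0.017,0.022,0.021,0.016,0.013,0.014,0.004
thyroid,0.020,0.018,0.016,0.022,0.021,0.015,0.012,0.013,0.004
urinary_bladder_wall,0.070,0.058,0.064,0.062,0.051,0.129,0.127,0.098,0.186
uterus,0.025,,,,,0.021,0.017,,0.010
lens_of_eyes,0.029,0.023,0.021,0.026,0.024,0.023,0.018,0.017,0.012
total_body,0.029,0.023,0.021,0.026,0.025,0.023,0.018,0.016,0.012
effective_dose_equivalent,0.058,0.047,0.044,0.051,0.045,0.054,0.040,0.035,0.046
effective_dose,0.046,0.038,0.036,0.040,0.035,0.043,0.030,0.029,0.032
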