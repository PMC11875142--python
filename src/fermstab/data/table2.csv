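ferm_id,strain,addiction_system,plasmid_size,dilution_rate,temperature,total_duration,stability_duration,cma_titer,specific_productivity,specific_uptake,yield_ps,yield_px,yield_xs
F1,CBC-tet,tet,3646,0.033,37,500,453,6.68,0.21,0.37,0.57,6.42,0.09
F2,CBC-tet,tet,3646,0.033,37,500,479,7.97,0.23,0.39,0.58,6.89,0.09
F3,CBC-tet,tet,3646,0.033,30,500,449,8.99,0.25,0.37,0.67,7.5,0.09
F4,CBC-tet,tet,3646,0.1,37,500,447,4.71,0.41,0.59,0.71,4.12,0.18
F5,CBC-proBA,proBA,6104,0.033,37,430,388,6.09,0.18,0.36,0.5,5.45,0.09
F6,CBC-proBA,proBA,6104,0.033,37,500,479,6.88,0.21,0.4,0.52,6.37,0.08
F7,CBC-proBA,proBA,6104,0.033,30,401,308,8.74,0.25,0.36,0.7,7.67,0.09
F8,CBC-proBA,proBA,6104,0.1,37,476,456,3.42,0.3,0.51,0.59,3.03,0.2
F9,CBC-ssb,ssb,3820,0.033,37,166,123,8.14,0.23,0.39,0.6,7.04,0.09
F10,CBC-ssb,ssb,3820,0.033,37,113,73,8.08,0.2,0.33,0.22,6.04,0.1
F11,CBC-ssb,ssb,3820,0.033,30,239,171,8.96,0.26,0.35,0.75,7.87,0.1
F12,CBC-ssb,ssb,3820,0.033,30,406,340,7.6,0.2,0.32,0.63,6.11,0.1
F13,CBC-ssb,ssb,3820,0.1,37,214,192,4.65,0.35,0.56,0.63,3.54,0.18
F14,CBC-ssb,ssb,3820,0.1,37,410,384,4.07,0.34,0.49,0.71,3.43,0.21
F15,CBC-infA,infA,4526,0.033,37,309,287,7.54,0.24,0.34,0.69,7.16,0.1
F16,CBC-infA,infA,4526,0.033,30,499,430,6.38,0.18,0.31,0.57,5.41,0.1
F17,CBC-infA,infA,4526,0.1,37,500,475,3.34,0.32,0.72,0.44,3.16,0.14
F18,CBC-infA,infA,4526,0.1,37,500,475,3.21,0.31,0.73,0.43,3.13,0.14
F19,CBC-infA,infA,4526,0.1,37,500,484,3.74,0.33,0.61,0.55,3.34,0.17
F20,CBC-dapD,dapD,4095,0.033,37,169,122,9.72,0.2,0.34,0.6,6.17,0.1
F21,CBC-dapD,dapD,4095,0.033,37,172,148,7.44,0.18,0.28,0.62,5.37,0.12
F22,CBC-dapD,dapD,4095,0.033,30,451,401,8.84,0.22,0.3,0.73,6.6,0.11
F23,CBC-dapD,dapD,4095,0.1,37,287,263,4.29,0.33,0.73,0.45,3.33,0.14
F24,CBC-dapD,dapD,4095,0.1,37,311,284,4.26,0.36,0.55,0.64,3.59,0.18
F25,CBC-dapD,dapD,4095,0.1,37,127,103,5.2,0.41,0.6,0.68,4.13,0.17
F26,CBC-proC,proC,4080,0.033,37,191,144,9.96,0.21,0.37,0.58,6.38,0.09
F27,CBC-proC,proC,4080,0.033,37,239,196,7.27,0.17,0.3,0.56,5.16,0.11
F28,CBC-proC,proC,4080,0.033,30,500,449,8.59,0.23,0.35,0.66,7.05,0.09
F29,CBC-proC,proC,4080,0.1,37,500,460,3.85,0.3,0.56,0.53,3.02,0.18
F30,CBC-unstabilized,none,3205,0.033,37,145,125,7.63,0.17,0.31,0.54,5.09,0.12
F31,CBC-unstabilized,none,3205,0.033,30,337,242,8.51,0.22,0.34,0.65,6.71,0.1
F32,CBC-unstabilized,none,3205,0.033,30,451,385,7.98,0.21,0.35,0.6,6.41,0.09
F33,CBC-unstabilized,none,3205,0.1,37,74,50,5.32,0.43,0.65,0.66,4.29,0.15
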