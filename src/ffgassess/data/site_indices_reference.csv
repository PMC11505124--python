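section,site_id,hbi_March,hbi_May,hbi_July,hbi_October,shannon_March,shannon_May,shannon_July,shannon_October
gorge,G1,3.03,4.40,2.50,3.20,1.0694,1.5825,0,1.0017
gorge,G2,2.50,3.38,2.51,2.50,0,1.3656,0.0526,0
gorge,G3,7.74,8.26,2.50,8.54,1.7297,1.4095,0,1.8375
gorge,G4,2.82,5.60,6.35,5.70,0.9052,1.9449,1.7210,1.9322
gorge,G5,3.25,4.40,3.66,2.55,1.0409,1.3639,1.1817,0.4912
gorge,G6,8.45,3.47,2.50,3.50,1.8710,1.6627,0,1.2935
gorge,G7,8.44,9.44,9.39,6.00,1.0699,0.7753,0.7993,1.5440
gorge,G8,5.75,8.11,8.76,4.63,1.2826,2.0560,1.2128,1.5774
gorge,G9,9.79,9.22,3.30,4.63,1.2155,1.0934,1.0548,2.2732
gorge,G10,3.98,3.66,2.99,5.97,1.7843,1.7415,0.8390,1.3049
gorge,G11,4.72,8.65,4.44,9.01,0.9757,0.9913,1.8955,0.8343
gorge,G12,4.77,4.81,6.63,8.79,1.7238,1.6669,1.8446,1.5579
gorge,G13,5.46,9.25,6.02,8.77,1.6088,2.0205,2.2824,0.9939
gorge,G14,5.54,5.55,4.94,5.62,1.7500,2.0121,1.8250,1.1596
gorge,G15,2.65,6.09,2.86,3.08,0.2762,1.5810,0.4983,0.9427
gorge,G16,4.47,8.40,4.04,6.38,1.9742,1.6821,2.0169,0.8443
gorge,G17,4.55,5.99,5.21,9.45,2.1051,2.0040,0.9013,0.8315
gorge,G18,5.33,4.89,2.91,5.99,0.7475,2.0223,0.7622,1.8464
plain,P1,2.60,7.14,3.43,4.59,0.7026,2.1147,1.1795,1.3303
plain,P2,4.49,7.95,3.79,6.93,1.4098,2.4468,2.4194,2.2859
plain,P3,7.77,5.07,6.34,4.63,1.8619,2.1299,2.5318,0.6508
plain,P4,8.35,7.59,8.87,5.19,1.9356,1.4924,1.3481,2.2788
plain,P5,8.65,4.78,9.37,7.87,1.0958,2.7962,0.8698,1.9306
plain,P6,5.09,6.30,2.56,6.91,0.8998,1.7152,0.2996,1.2210
plain,P7,3.69,7.29,5.02,8.03,1.4210,2.2356,1.7527,1.5016
plain,P8,7.96,7.63,4.80,5.65,2.1473,1.8724,1.6930,1.7161
plain,P9,5.04,6.80,5.41,6.34,1.9593,1.8341,1.3965,1.5991
plain,P10,6.96,7.63,5.02,4.09,1.3796,1.2988,1.2509,1.3101
plain,P11,6.58,4.44,5.00,5.78,1.8911,1.4098,1.9610,1.4565
plain,P12,9.29,3.84,7.78,4.71,0.8841,2.4235,2.6426,2.5771
plain,P13,4.62,5.57,5.08,5.37,1.0995,1.7971,1.9046,2.4911
plain,P14,5.07,5.63,4.13,4.56,1.1596,2.0230,0.9226,2.3938
plain,P15,4.09,4.58,4.47,3.92,0.2762,2.4695,1.4864,1.3998
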