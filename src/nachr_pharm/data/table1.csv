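receptor,ligand,pec50_mean,pec50_se,imax_mean,imax_se,n,core_panel
Da1/Db1,ACh,5.24,0.04,1.0,0.0,5,True
Da1/Db1,imidacloprid,7.16,0.15,0.122,0.007,5,True
Da1/Db1,thiacloprid,7.79,0.21,0.091,0.009,5,True
Da1/Db1,clothianidin,7.13,0.10,0.508,0.015,5,True
Da3/Db1,ACh,6.14,0.06,1.0,0.0,5,True
Da3/Db1,imidacloprid,8.32,0.21,0.032,0.003,5,True
Da3/Db1,thiacloprid,7.80,0.08,0.016,0.001,5,True
Da3/Db1,clothianidin,7.54,0.04,0.691,0.013,5,True
Da1/Da3/Db1,ACh,5.85,0.03,1.0,0.0,5,True
Da1/Da3/Db1,imidacloprid,7.58,0.23,0.170,0.020,5,True
Da1/Da3/Db1,thiacloprid,8.07,0.20,0.047,0.006,5,True
Da1/Da3/Db1,clothianidin,7.20,0.09,0.627,0.025,5,True
Da1/Da2/Db1,ACh,4.14,0.05,1.0,0.0,5,True
Da1/Da2/Db1,imidacloprid,6.71,0.14,0.031,0.002,5,True
Da1/Da2/Db1,thiacloprid,6.92,0.08,0.025,0.001,5,True
Da1/Da2/Db1,clothianidin,5.07,0.11,0.699,0.034,5,True
Da2/Da3/Db1,ACh,5.45,0.07,1.0,0.0,5,True
Da2/Da3/Db1,imidacloprid,6.88,0.29,0.101,0.016,5,True
Da2/Da3/Db1,thiacloprid,6.92,0.19,0.045,0.006,5,True
Da2/Da3/Db1,clothianidin,6.81,0.08,0.882,0.076,5,True
Da1/Da2/Da3/Db1,ACh,5.43,0.05,1.0,0.0,5,True
Da1/Da2/Da3/Db1,imidacloprid,7.08,0.15,0.094,0.007,5,True
Da1/Da2/Da3/Db1,thiacloprid,7.73,0.19,0.047,0.004,5,True
Da1/Da2/Da3/Db1,clothianidin,6.55,0.07,0.817,0.024,5,True
Da1/Db1/Db2,ACh,4.75,0.04,1.0,0.0,5,True
Da1/Db1/Db2,imidacloprid,6.99,0.18,0.076,0.006,5,True
Da1/Db1/Db2,thiacloprid,7.86,0.10,0.043,0.002,5,True
Da1/Db1/Db2,clothianidin,6.64,0.10,0.360,0.016,5,True
Da3/Db1/Db2,ACh,6.19,0.07,1.0,0.0,5,True
Da3/Db1/Db2,imidacloprid,8.28,0.09,0.039,0.002,5,True
Da3/Db1/Db2,thiacloprid,8.32,0.21,0.022,0.003,5,True
Da3/Db1/Db2,clothianidin,7.46,0.08,0.492,0.016,5,True
Da1/Da3/Db1/Db2,ACh,6.43,0.02,1.0,0.0,5,True
Da1/Da3/Db1/Db2,imidacloprid,7.52,0.12,0.330,0.018,5,True
Da1/Da3/Db1/Db2,thiacloprid,8.00,0.25,0.107,0.015,5,True
Da1/Da3/Db1/Db2,clothianidin,7.40,0.07,0.684,0.022,5,True
Da1/Da2/Db1/Db2,ACh,4.92,0.05,1.0,0.0,5,True
Da1/Da2/Db1/Db2,imidacloprid,6.45,0.21,0.165,0.016,5,True
Da1/Da2/Db1/Db2,thiacloprid,7.10,0.30,0.074,0.014,5,True
Da1/Da2/Db1/Db2,clothianidin,6.31,0.10,0.800,0.033,5,True
Da2/Da3/Db1/Db2,ACh,5.99,0.07,1.0,0.0,5,True
Da2/Da3/Db1/Db2,imidacloprid,7.00,0.29,0.125,0.018,5,True
Da2/Da3/Db1/Db2,thiacloprid,8.08,0.33,0.017,0.002,5,True
Da2/Da3/Db1/Db2,clothianidin,7.29,0.07,0.634,0.020,5,True
Da1/Da2/Da3/Db1/Db2,ACh,4.49,0.04,1.0,0.0,5,True
Da1/Da2/Da3/Db1/Db2,imidacloprid,6.47,0.14,0.142,0.011,5,True
Da1/Da2/Da3/Db1/Db2,thiacloprid,7.18,0.17,0.059,0.006,5,True
Da1/Da2/Da3/Db1/Db2,clothianidin,6.59,0.07,0.812,0.019,5,True
Da2/Da3/Da4/Db1/Db2,ACh,5.49,0.06,1.0,0.0,5,False
Da2/Da3/Da4/Db1/Db2,imidacloprid,7.40,0.20,0.027,0.002,5,False
Da2/Da3/Da4/Db1/Db2,thiacloprid,7.99,0.20,0.018,0.002,5,False
Da2/Da3/Da4/Db1/Db2,clothianidin,7.11,0.12,0.912,0.041,5,False
Da2/Da3/Db1/Db2/Db3,ACh,6.01,0.04,1.0,0.0,5,False
Da2/Da3/Db1/Db2/Db3,imidacloprid,7.75,0.31,0.021,0.003,5,False
Da2/Da3/Db1/Db2/Db3,thiacloprid,8.31,0.17,0.010,0.001,5,False
Da2/Da3/Db1/Db2/Db3,clothianidin,7.46,0.06,0.695,0.014,5,False
Da1/Da3/Da4/Db1/Db2,ACh,4.79,0.04,1.0,0.0,5,False
Da1/Da3/Da4/Db1/Db2,imidacloprid,7.30,0.17,0.101,0.008,5,False
Da1/Da3/Da4/Db1/Db2,thiacloprid,7.96,0.10,0.026,0.001,5,False
Da1/Da3/Da4/Db1/Db2,clothianidin,6.94,0.06,0.425,0.008,5,False
Da1/Da3/Db1/Db2/Db3,ACh,5.83,0.02,1.0,0.0,5,False
Da1/Da3/Db1/Db2/Db3,imidacloprid,7.72,0.11,0.140,0.008,5,False
Da1/Da3/Db1/Db2/Db3,thiacloprid,8.63,0.23,0.089,0.009,5,False
Da1/Da3/Db1/Db2/Db3,clothianidin,7.60,0.12,0.531,0.026,5,False
Da1/Da2/Da4/Db1/Db2,ACh,4.64,0.05,1.0,0.0,5,False
Da1/Da2/Da4/Db1/Db2,imidacloprid,6.48,0.28,0.172,0.020,5,False
Da1/Da2/Da4/Db1/Db2,thiacloprid,7.01,0.19,0.066,0.007,5,False
Da1/Da2/Da4/Db1/Db2,clothianidin,6.72,0.09,1.001,0.031,5,False
Da1/Da2/Db1/Db2/Db3,ACh,4.42,0.02,1.0,0.0,5,False
Da1/Da2/Db1/Db2/Db3,imidacloprid,6.27,0.21,0.080,0.007,5,False
Da1/Da2/Db1/Db2/Db3,thiacloprid,7.71,0.43,0.023,0.004,5,False
Da1/Da2/Db1/Db2/Db3,clothianidin,5.67,0.11,0.974,0.041,5,False
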