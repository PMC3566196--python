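subject_id,group,pair_id,age,sex,csf_sv,ptp_pg,icvc,mricp
MTBI_01,mTBI,PAIR_01,20,m,0.70,0.053,0.58,14.9
MTBI_02,mTBI,PAIR_02,22,f,0.51,0.054,0.41,16.4
MTBI_03,mTBI,PAIR_03,23,m,0.72,0.043,0.49,10.6
MTBI_04,mTBI,PAIR_04,23,m,0.47,0.042,0.36,11.7
MTBI_05,mTBI,PAIR_05,23,f,0.70,0.034,0.54,9.1
MTBI_06,mTBI,PAIR_06,24,m,0.65,0.048,0.53,10.6
MTBI_07,mTBI,PAIR_07,25,m,0.30,0.030,0.53,9.6
MTBI_08,mTBI,PAIR_08,25,m,0.98,0.036,0.69,8.7
MTBI_09,mTBI,PAIR_09,27,m,0.66,0.053,0.64,12.1
MTBI_10,mTBI,PAIR_10,27,m,0.21,0.053,0.31,16.7
MTBI_11,mTBI,PAIR_11,29,m,0.54,0.047,0.49,14.9
MTBI_12,mTBI,PAIR_12,29,m,0.56,0.050,0.44,15.5
MTBI_13,mTBI,PAIR_13,32,f,0.60,0.030,0.33,11.2
MTBI_14,mTBI,PAIR_14,33,m,0.59,0.045,0.55,9.2
MTBI_15,mTBI,PAIR_15,49,f,0.54,0.034,0.26,15.7
CTR_01,control,PAIR_01,18,m,0.84,0.054,0.82,10.4
CTR_02,control,PAIR_02,22,f,0.41,0.031,0.50,9.3
CTR_03,control,PAIR_03,23,m,0.60,0.049,0.57,9.1
CTR_04,control,PAIR_04,23,m,0.50,0.031,0.77,5.8
CTR_05,control,PAIR_05,24,f,0.40,0.022,0.27,10.7
CTR_06,control,PAIR_06,24,m,0.69,0.069,0.74,10.4
CTR_07,control,PAIR_07,24,m,0.63,0.023,0.56,7.4
CTR_08,control,PAIR_08,25,m,0.41,0.054,0.52,13.8
CTR_09,control,PAIR_09,26,m,0.56,0.056,0.97,7.5
CTR_10,control,PAIR_10,26,m,0.53,0.041,0.64,9.2
CTR_11,control,PAIR_11,27,m,0.60,0.058,0.85,7.6
CTR_13,control,PAIR_13,30,m,0.41,0.030,0.44,6.7
CTR_12,control,PAIR_12,32,f,0.48,0.031,0.44,8.0
CTR_14,control,PAIR_14,32,m,0.80,0.042,0.83,6.7
CTR_15,control,PAIR_15,48,f,0.21,0.023,0.27,8.6
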