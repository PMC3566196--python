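subject_id,group,pair_id,age,sex,tcbf,jvf,jvf_pct,dcv_pct,vv_pct,ev_pct,svf_total_pct,mrv_grade
MTBI_01,mTBI,PAIR_01,20,m,883,696,78.8,0.4,0.0,1.9,2.3,3
MTBI_02,mTBI,PAIR_02,22,f,966,564,58.4,8.0,5.5,1.4,14.9,5
MTBI_03,mTBI,PAIR_03,23,m,1020,718,70.4,0.0,1.3,6.0,7.3,3
MTBI_04,mTBI,PAIR_04,23,m,586,480,81.9,0.0,0.0,5.8,5.8,4
MTBI_05,mTBI,PAIR_05,23,f,797,484,60.7,12.4,1.7,0.0,14.0,4
MTBI_06,mTBI,PAIR_06,24,m,873,423,48.5,1.5,22.4,2.5,26.4,5
MTBI_07,mTBI,PAIR_07,25,m,694,355,51.2,3.7,2.3,2.8,8.9,4
MTBI_08,mTBI,PAIR_08,25,m,790,601,76.0,1.3,0.2,0.0,2.8,3
MTBI_09,mTBI,PAIR_09,27,m,1192,849,71.2,1.7,3.3,0.9,5.9,4
MTBI_10,mTBI,PAIR_10,27,m,704,381,54.2,4.8,1.0,11.3,17.1,5
MTBI_11,mTBI,PAIR_11,29,m,880,792,90.1,0.0,0.0,0.0,0.0,2
MTBI_12,mTBI,PAIR_12,29,m,791,355,44.9,12.0,0.0,2.4,14.4,5
MTBI_13,mTBI,PAIR_13,32,f,727,479,65.8,10.0,0.0,0.7,10.8,n.a.
MTBI_14,mTBI,PAIR_14,33,m,848,0,0.0,10.9,9.6,22.7,43.2,5
MTBI_15,mTBI,PAIR_15,49,f,826,511,61.9,10.1,0.0,0.2,10.3,4
CTR_01,control,PAIR_01,18,m,911,599,65.7,3.7,2.3,3.9,9.9,4
CTR_02,control,PAIR_02,22,f,575,382,66.4,5.0,2.9,1.0,8.9,4
CTR_03,control,PAIR_03,23,m,688,490,71.2,3.7,0.0,1.9,5.6,n.a.
CTR_04,control,PAIR_04,23,m,831,747,89.9,1.8,0.0,2.5,4.4,2
CTR_05,control,PAIR_05,24,f,809,548,67.7,1.3,0.0,0.0,1.3,2
CTR_06,control,PAIR_06,24,m,819,740,90.4,0.0,0.0,3.1,3.1,3
CTR_07,control,PAIR_07,24,m,888,753,84.9,0.0,1.4,3.0,4.3,2
CTR_08,control,PAIR_08,25,m,797,693,86.9,0.0,0.0,2.5,2.5,2
CTR_09,control,PAIR_09,26,m,904,723,80.0,7.4,0.0,0.0,7.4,4
CTR_10,control,PAIR_10,26,m,716,421,58.9,6.0,0.0,5.8,11.9,n.a.
CTR_11,control,PAIR_11,27,m,842,706,83.8,2.8,0.5,0.0,3.3,2
CTR_13,control,PAIR_13,30,m,591,444,75.2,2.8,0.0,0.0,2.8,3
CTR_12,control,PAIR_12,32,f,687,453,66.0,1.2,0.0,0.0,1.2,2
CTR_14,control,PAIR_14,32,m,917,774,84.3,7.5,0.8,0.5,8.8,4
CTR_15,control,PAIR_15,48,f,718,583,81.2,3.3,0.0,3.2,6.5,3
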