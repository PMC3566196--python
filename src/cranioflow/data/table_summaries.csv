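table,variable,group,statistic,printed,decimals,input_decimals
1,tcbf,mTBI,mean,838,0,0
1,tcbf,control,mean,779,0,0
1,jvf,mTBI,mean,513,0,0
1,jvf,control,mean,604,0,0
1,jvf_pct,mTBI,mean,60.9,1,1
1,jvf_pct,control,mean,76.8,1,1
1,dcv_pct,mTBI,mean,5.1,1,1
1,dcv_pct,control,mean,3.1,1,1
1,vv_pct,mTBI,mean,3.2,1,1
1,vv_pct,control,mean,0.5,1,1
1,ev_pct,mTBI,mean,3.9,1,1
1,ev_pct,control,mean,1.8,1,1
1,svf_total_pct,mTBI,mean,12.3,1,1
1,svf_total_pct,control,mean,5.5,1,1
1,mrv_grade,mTBI,mean,4.0,1,0
1,mrv_grade,control,mean,2.8,1,0
1,mrv_grade,mTBI,median,4,0,0
1,mrv_grade,control,median,3,0,0
2,csf_sv,mTBI,mean,0.58,2,2
2,csf_sv,control,mean,0.54,2,2
2,ptp_pg,mTBI,mean,0.043,3,3
2,ptp_pg,control,mean,0.041,3,3
2,icvc,mTBI,mean,0.48,2,2
2,icvc,control,mean,0.61,2,2
2,mricp,mTBI,mean,12.46,2,1
2,mricp,control,mean,8.77,2,1
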