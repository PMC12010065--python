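patient_id,gene,sex,onset_age,surgery_age,bfmdrs_pre,bfmdrs_fu1,bfmdrs_fu3,bfmdrs_fu5
Pat1,VPS16,F,12,23,23.0,13.5,19.5,18.5
Pat2,VPS16,M,15,43,32.0,15.5,18.5,17.5
Pat3,SGCE,F,2,33,54.5,19.0,9.0,15.5
Pat4,VPS16,M,14,49,52.5,22.5,9.0,11.0
Pat5,VPS16,F,13,41,88.0,28.0,20.0,23.0
Pat6,AOPEP,M,12,20,63.0,65.0,38.5,40.0
Pat7,SGCE,F,10,20,12.0,8.0,9.0,8.0
Pat8,THAP1,F,40,48,17.0,20.0,16.0,18.0
Pat9,THAP1,F,7,17,32.5,5.0,5.5,7.0
Pat10,THAP1,M,6,14,45.0,20.0,23.0,23.0
Pat11,THAP1,M,14,32,60.5,31.0,26.5,22.0
Pat12,PANK2,F,16,25,89.5,80.0,76.0,76.0
Pat13,KMT2B,M,28,45,27.0,10.0,13.5,8.5
Pat14,TOR1A,M,12,45,39.0,5.0,8.5,8.0
Pat15,TOR1A,M,13,43,29.5,4.0,14.0,16.0
Pat16,TOR1A,F,7,9,43.0,4.0,4.0,4.0
Pat17,TOR1A,M,10,49,25.0,18.0,,
Pat18,TOR1A,M,12,33,36.0,19.0,9.0,8.0
Pat19,TOR1A,M,10,47,23.5,10.0,19.0,9.0
Pat20,TOR1A,F,11,44,59.0,17.5,19.5,11.0
Pat21,TOR1A,M,14,46,30.5,24.5,9.0,
Pat22,TOR1A,M,8,9,34.0,3.0,6.0,
Pat23,KMT2B,M,8,16,28.0,14.0,17.0,15.0
Pat24,SGCE,M,2,29,11.5,10.5,,
Pat25,SGCE,M,3,14,16.0,2.5,,
Pat26,GNAL,F,37,42,26.0,22.0,20.0,13.0
Pat27,GNAL,F,42,63,24.0,14.0,16.0,13.0
Pat28,PANK2,F,2,10,78.5,74.5,78.5,70.5
Pat29,PANK2,M,2,6,96.0,80.0,77.0,
Pat30,VPS16,M,11,19,25.0,19.0,19.0,34.0
Pat31,PLA2G6,F,28,34,66.5,60.5,58.5,
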