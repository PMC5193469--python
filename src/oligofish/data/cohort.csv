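case_id,group,age,sex,recurrence,mvp,calcifications,mitoses_per_10hpf,ki67_pct,ina_positive,idh1r132h_positive,idh2_mutant,atrx,necrosis,status_1p,status_19q,status_9p,status_10q,control_9q_deleted,control_10p_deleted
C01,OII,30,M,True,endocrinoid,True,0,10,True,True,False,retained,False,DELETED,DELETED,IMBALANCED,NORMAL,False,False
C02,OII,33,M,False,endocrinoid,False,0,10,True,True,False,retained,False,DELETED,DELETED,IMBALANCED,NORMAL,False,False
C03,OII,36,M,False,endocrinoid,True,1,10,True,True,False,retained,False,DELETED,DELETED,NORMAL,IMBALANCED,False,False
C04,OII,38,M,False,endocrinoid,False,1,10,True,True,False,retained,False,DELETED,DELETED,NORMAL,IMBALANCED,False,False
C05,OII,40,M,False,endocrinoid,True,1,10,True,True,False,retained,False,DELETED,DELETED,NORMAL,NORMAL,False,False
C06,OII,42,M,False,endocrinoid,False,2,10,True,True,False,retained,False,DELETED,DELETED,NORMAL,NORMAL,False,False
C07,OII,42,M,False,endocrinoid,True,2,10,True,True,False,retained,False,DELETED,DELETED,NORMAL,NORMAL,False,False
C08,OII,42,M,False,endocrinoid,False,2,10,True,True,False,retained,False,DELETED,DELETED,NORMAL,NORMAL,False,False
C09,OII,45,F,False,endocrinoid,True,2,10,True,True,False,retained,False,DELETED,DELETED,NORMAL,NORMAL,False,False
C10,OII,50,F,False,endocrinoid,False,2,10,True,True,False,retained,False,DELETED,DELETED,NORMAL,NORMAL,False,False
C11,OII,55,F,False,endocrinoid,False,3,10,True,True,False,retained,False,DELETED,DELETED,NORMAL,NORMAL,False,False
C12,OII,60,F,False,endocrinoid,False,3,10,False,True,False,retained,False,DELETED,DELETED,NORMAL,NORMAL,False,False
C13,OII,72,F,False,endocrinoid,False,3,10,False,False,True,retained,False,DELETED,DELETED,NORMAL,NORMAL,False,False
C14,OIII,32,M,True,glomeruloid,True,4,21,True,True,False,retained,False,DELETED,DELETED,DELETED,NORMAL,True,False
C15,OIII,36,M,True,glomeruloid,False,5,21,True,True,False,retained,False,DELETED,DELETED,DELETED,NORMAL,True,False
C16,OIII,40,M,False,glomeruloid,True,5,21,True,True,False,retained,False,DELETED,DELETED,DELETED,NORMAL,False,False
C17,OIII,42,M,False,glomeruloid,False,6,21,True,True,False,retained,False,DELETED,DELETED,DELETED,NORMAL,False,False
C18,OIII,44,M,False,glomeruloid,True,6,21,True,True,False,retained,False,DELETED,DELETED,DELETED,NORMAL,False,False
C19,OIII,44,M,False,glomeruloid,False,6,21,True,True,False,retained,False,DELETED,DELETED,DELETED,NORMAL,False,False
C20,OIII,46,F,False,glomeruloid,True,7,21,True,True,False,retained,False,DELETED,DELETED,DELETED,NORMAL,False,False
C21,OIII,50,F,False,glomeruloid,False,8,21,True,True,False,retained,False,DELETED,DELETED,NORMAL,IMBALANCED,False,False
C22,OIII,58,F,False,glomeruloid,True,10,21,False,True,False,retained,False,DELETED,DELETED,NORMAL,NORMAL,False,False
C23,OIII,78,F,False,glomeruloid,False,13,21,False,True,False,retained,False,DELETED,DELETED,IMBALANCED,NORMAL,False,False
C24,AII,35,F,True,endocrinoid,False,0,8,False,True,False,lost,False,DELETED,IMBALANCED,NORMAL,NORMAL,False,False
C25,AII,38,F,False,endocrinoid,False,0,8,False,True,False,retained,False,IMBALANCED,IMBALANCED,IMBALANCED,NORMAL,False,False
C26,AII,41,F,False,endocrinoid,False,0,8,False,True,False,retained,False,IMBALANCED,IMBALANCED,NORMAL,IMBALANCED,False,False
C27,AIII,33,M,True,endocrinoid,True,3,8,False,True,False,lost,False,DELETED,NORMAL,IMBALANCED,NORMAL,False,False
C28,AIII,35,M,True,endocrinoid,True,3,8,False,True,False,lost,False,NORMAL,NORMAL,NORMAL,NORMAL,False,False
C29,AIII,49,F,True,endocrinoid,False,5,8,False,True,False,retained,False,IMBALANCED,IMBALANCED,NORMAL,NORMAL,False,False
C30,GBM,38,M,False,glomeruloid,False,2,15,True,True,False,retained,False,DELETED,NORMAL,DELETED,DELETED,False,False
C31,GBM,42,M,False,glomeruloid,False,5,20,False,False,False,lost,False,IMBALANCED,IMBALANCED,DELETED,DELETED,False,False
C32,GBM,44,F,False,glomeruloid,False,5,20,False,False,False,retained,False,NORMAL,NORMAL,DELETED,NORMAL,False,False
C33,GBM,52,F,False,glomeruloid,False,5,37,False,False,False,retained,False,NORMAL,NORMAL,DELETED,NORMAL,False,False
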