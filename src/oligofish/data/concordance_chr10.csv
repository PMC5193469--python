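case_id,chromosome,manual,automated,interpretable
C01,chr10,NORMAL,NORMAL,True
C02,chr10,NORMAL,IMBALANCED,False
C03,chr10,IMBALANCED,NORMAL,True
C04,chr10,IMBALANCED,IMBALANCED,True
C05,chr10,NORMAL,NORMAL,True
C06,chr10,NORMAL,IMBALANCED,True
C07,chr10,NORMAL,NORMAL,True
C08,chr10,NORMAL,DELETED,False
C09,chr10,NORMAL,NORMAL,True
C10,chr10,NORMAL,NORMAL,True
C11,chr10,NORMAL,NORMAL,True
C12,chr10,NORMAL,NORMAL,True
C13,chr10,NORMAL,IMBALANCED,True
C14,chr10,NORMAL,NORMAL,True
C15,chr10,NORMAL,IMBALANCED,False
C16,chr10,NORMAL,NORMAL,True
C17,chr10,NORMAL,IMBALANCED,True
C18,chr10,NORMAL,NORMAL,True
C19,chr10,NORMAL,NORMAL,True
C20,chr10,NORMAL,NORMAL,True
C21,chr10,IMBALANCED,NORMAL,True
C22,chr10,NORMAL,NORMAL,True
C23,chr10,NORMAL,NORMAL,True
C24,chr10,NORMAL,NORMAL,True
C25,chr10,NORMAL,NORMAL,True
C26,chr10,IMBALANCED,DELETED,True
C27,chr10,NORMAL,NORMAL,True
C28,chr10,NORMAL,NORMAL,True
C29,chr10,NORMAL,IMBALANCED,False
C30,chr10,DELETED,DELETED,True
C31,chr10,DELETED,DELETED,True
C32,chr10,NORMAL,NORMAL,True
C33,chr10,NORMAL,NORMAL,False
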