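case_id,chromosome,manual,automated,interpretable
C01,chr9,IMBALANCED,NORMAL,True
C02,chr9,IMBALANCED,IMBALANCED,True
C03,chr9,NORMAL,NORMAL,True
C04,chr9,NORMAL,NORMAL,True
C05,chr9,NORMAL,IMBALANCED,True
C06,chr9,NORMAL,NORMAL,True
C07,chr9,NORMAL,NORMAL,True
C08,chr9,NORMAL,NORMAL,True
C09,chr9,NORMAL,NORMAL,True
C10,chr9,NORMAL,NORMAL,True
C11,chr9,NORMAL,NORMAL,True
C12,chr9,NORMAL,IMBALANCED,False
C13,chr9,NORMAL,NORMAL,True
C14,chr9,DELETED,DELETED,True
C15,chr9,DELETED,DELETED,True
C16,chr9,DELETED,IMBALANCED,True
C17,chr9,DELETED,DELETED,True
C18,chr9,DELETED,DELETED,True
C19,chr9,DELETED,DELETED,True
C20,chr9,DELETED,DELETED,True
C21,chr9,NORMAL,NORMAL,True
C22,chr9,NORMAL,DELETED,False
C23,chr9,IMBALANCED,IMBALANCED,True
C24,chr9,NORMAL,IMBALANCED,True
C25,chr9,IMBALANCED,IMBALANCED,True
C26,chr9,NORMAL,NORMAL,True
C27,chr9,IMBALANCED,NORMAL,True
C28,chr9,NORMAL,NORMAL,True
C29,chr9,NORMAL,NORMAL,True
C30,chr9,DELETED,DELETED,True
C31,chr9,DELETED,IMBALANCED,True
C32,chr9,DELETED,DELETED,True
C33,chr9,DELETED,DELETED,True
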