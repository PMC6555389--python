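Identifier,Protein_ID,Peptide_Seq,Total_Sites,PTM_Loc,PTM_Score
id1,P10001,QISFVK,1,S3,99.5
id2,P10002,SSRAGLQFPVGR,2,S1;S2,98.0;97.0
id3,P10003,VYYFNHITNASQWER,1,Y2;Y3,55.0;45.0
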