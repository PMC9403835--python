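brain,sex,hemisphere,area,volume_mm3
BC04,M,left,SFS1,285
BC04,M,left,SFS2,209
BC04,M,left,MFG1,518
BC04,M,left,MFG2,239
BC04,M,right,SFS1,235
BC04,M,right,SFS2,254
BC04,M,right,MFG1,451
BC04,M,right,MFG2,469
BC11,M,left,SFS1,358
BC11,M,left,SFS2,269
BC11,M,left,MFG1,956
BC11,M,left,MFG2,598
BC11,M,right,SFS1,341
BC11,M,right,SFS2,362
BC11,M,right,MFG1,672
BC11,M,right,MFG2,978
BC13,M,left,SFS1,550
BC13,M,left,SFS2,354
BC13,M,left,MFG1,852
BC13,M,left,MFG2,791
BC13,M,right,SFS1,232
BC13,M,right,SFS2,263
BC13,M,right,MFG1,465
BC13,M,right,MFG2,531
BC20,M,left,SFS1,321
BC20,M,left,SFS2,179
BC20,M,left,MFG1,521
BC20,M,left,MFG2,885
BC20,M,right,SFS1,438
BC20,M,right,SFS2,277
BC20,M,right,MFG1,591
BC20,M,right,MFG2,431
BC21,M,left,SFS1,492
BC21,M,left,SFS2,196
BC21,M,left,MFG1,798
BC21,M,left,MFG2,799
BC21,M,right,SFS1,346
BC21,M,right,SFS2,174
BC21,M,right,MFG1,603
BC21,M,right,MFG2,454
BC05,F,left,SFS1,601
BC05,F,left,SFS2,403
BC05,F,left,MFG1,787
BC05,F,left,MFG2,404
BC05,F,right,SFS1,655
BC05,F,right,SFS2,399
BC05,F,right,MFG1,803
BC05,F,right,MFG2,368
BC08,F,left,SFS1,279
BC08,F,left,SFS2,269
BC08,F,left,MFG1,713
BC08,F,left,MFG2,463
BC08,F,right,SFS1,355
BC08,F,right,SFS2,216
BC08,F,right,MFG1,667
BC08,F,right,MFG2,496
BC09,F,left,SFS1,327
BC09,F,left,SFS2,357
BC09,F,left,MFG1,894
BC09,F,left,MFG2,404
BC09,F,right,SFS1,374
BC09,F,right,SFS2,219
BC09,F,right,MFG1,910
BC09,F,right,MFG2,491
BC10,F,left,SFS1,253
BC10,F,left,SFS2,254
BC10,F,left,MFG1,477
BC10,F,left,MFG2,387
BC10,F,right,SFS1,332
BC10,F,right,SFS2,329
BC10,F,right,MFG1,1156
BC10,F,right,MFG2,517
BC14,F,left,SFS1,347
BC14,F,left,SFS2,399
BC14,F,left,MFG1,476
BC14,F,left,MFG2,362
BC14,F,right,SFS1,422
BC14,F,right,SFS2,396
BC14,F,right,MFG1,595
BC14,F,right,MFG2,617
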