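compound,target,ic50_uM,ci_low_uM,ci_high_uM,atp_uM
1,CDK1,14,8,27,1
1,CDK2,0.71,0.64,0.80,1
1,CDK5,40,27,59,1
1,CDK9,3.0,1.7,5.3,1
2,CDK1,0.72,0.54,0.96,1
2,CDK2,0.16,0.13,0.19,1
2,CDK5,0.88,0.65,1.19,1
2,CDK9,1.0,0.7,1.5,1
3,CDK1,30,19,49,1
3,CDK2,1.2,1.0,1.3,1
3,CDK5,79,49,126,1
3,CDK9,4.3,3.0,6.1,1
4,CDK1,6.2,4.0,9.9,1
4,CDK2,0.27,0.24,0.31,1
4,CDK5,20,16,25,1
4,CDK9,0.88,0.83,0.94,1
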