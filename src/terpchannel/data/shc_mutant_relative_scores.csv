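enzyme,intermediate,score
1SQC-wild,A-I1,0.0
1SQC-wild,A-I2,0.0
1SQC-wild,A-I3,0.0
1SQC-wild,A-I4,0.0
1SQC-Y609C,A-I1,3.7
1SQC-Y609C,A-I2,2.0
1SQC-Y609C,A-I3,32.1
1SQC-Y609C,A-I4,1.7
1SQC-Y609L,A-I1,-1.0
1SQC-Y609L,A-I2,-2.9
1SQC-Y609L,A-I3,NP
1SQC-Y609L,A-I4,0.5
1SQC-Y609S,A-I1,-3.1
1SQC-Y609S,A-I2,3.0
1SQC-Y609S,A-I3,NP
1SQC-Y609S,A-I4,0.9
1SQC-L607K,A-I1,13.9
1SQC-L607K,A-I2,NP
1SQC-L607K,A-I3,NP
1SQC-L607K,A-I4,NP
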