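name,conductance_nS,diameter_nm,strands
peak1,1.1,1.7,13.8
peak2,3.3,3.0,19.8
peak3,7.0,4.4,26.6
peak4,10.5,5.4,31.6
peak5,14.4,6.3,36.4
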