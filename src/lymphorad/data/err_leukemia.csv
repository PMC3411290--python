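beta_male,beta_female,theta,gamma,delta,phi
1.1,1.2,0.87,-0.40,-0.48,0.42
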