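site,beta_male,beta_female,gamma,eta
stomach,0.21,0.48,-0.30,-1.4
colon,0.63,0.43,-0.30,-1.4
liver,0.32,0.32,-0.30,-1.4
lung,0.32,1.40,-0.30,-1.4
breast,0.0,0.51,-0.30,-1.4
prostate,0.12,0.0,-0.30,-1.4
uterus,0.0,0.055,-0.30,-1.4
ovary,0.0,0.38,-0.30,-1.4
bladder,0.50,1.65,-0.30,-1.4
other_solid,0.27,0.45,-0.30,-1.4
thyroid,0.53,1.05,-0.30,-1.4
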