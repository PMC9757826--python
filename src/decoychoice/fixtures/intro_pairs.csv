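subject,trial,condition,hx,hp,lx,lp,dx,dp,choice,rt
s1,0,binary,1.0,0.9,1.0,0.8,,,none,
s1,1,binary,0.5,0.5,0.5,0.3,,,none,
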