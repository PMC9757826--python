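subject,trial,condition,hx,hp,lx,lp,dx,dp,choice,rt,proximity,dominance
s1,0,ternary,0.6,0.7,0.75,0.5,0.5,0.6,none,,H,inferior
s1,1,ternary,0.6,0.7,0.75,0.5,0.55,0.62,none,,H,inferior
s1,2,ternary,0.6,0.7,0.75,0.5,0.52,0.66,none,,H,inferior
s1,3,ternary,0.6,0.7,0.75,0.5,0.7,0.75,none,,H,superior
s1,4,ternary,0.6,0.7,0.75,0.5,0.68,0.78,none,,H,superior
s1,5,ternary,0.6,0.7,0.75,0.5,0.72,0.7,none,,H,superior
s1,6,ternary,0.6,0.7,0.75,0.5,0.65,0.4,none,,L,inferior
s1,7,ternary,0.6,0.7,0.75,0.5,0.7,0.42,none,,L,inferior
s1,8,ternary,0.6,0.7,0.75,0.5,0.68,0.38,none,,L,inferior
s1,9,ternary,0.6,0.7,0.75,0.5,0.85,0.55,none,,L,superior
s1,10,ternary,0.6,0.7,0.75,0.5,0.8,0.58,none,,L,superior
s1,11,ternary,0.6,0.7,0.75,0.5,0.82,0.52,none,,L,superior
s1,12,binary,0.6,0.7,0.75,0.5,,,none,,,
s1,13,binary,0.6,0.7,0.75,0.5,,,none,,,
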