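predicted,scc,dysplasia,normal,background
scc,604,0,0,51
dysplasia,0,594,0,55
normal,0,0,546,63
background,50,84,66,0
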