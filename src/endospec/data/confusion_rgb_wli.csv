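predicted,scc,dysplasia,normal,background
scc,521,0,0,39
dysplasia,0,559,0,75
normal,0,0,514,63
background,145,185,128,0
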