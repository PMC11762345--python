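predicted,scc,dysplasia,normal,background
scc,589,0,0,32
dysplasia,0,641,0,50
normal,0,0,535,49
background,77,103,107,0
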