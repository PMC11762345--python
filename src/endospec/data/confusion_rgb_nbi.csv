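predicted,scc,dysplasia,normal,background
scc,581,0,0,47
dysplasia,0,571,0,42
normal,0,0,526,71
background,73,107,86,0
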