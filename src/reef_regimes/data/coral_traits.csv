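species,trait_class
Porites lobata,stress-tolerant
Pocillopora meandrina,competitive
Porites compressa,weedy
Montipora capitata,competitive
other coral,generalist
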