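category,group
Porites lobata,coral
Porites compressa,coral
Pocillopora meandrina,coral
Montipora capitata,coral
other coral,coral
macroalgae,macroalgae
turf,turf
cca,cca
sand,other_cover
rock,other_cover
sponge,other_cover
dead coral,other_cover
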