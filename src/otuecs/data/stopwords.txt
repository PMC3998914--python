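# Generic annotation tokens carrying no ecological signal; one per line.
# Edit freely -- this list is loaded at run time.
sample
samples
environmental
environment
clone
clones
uncultured
unidentified
bacterium
bacteria
archaeon
isolate
strain
sp
dna
rrna
gene
16s
18s
ssu
partial
sequence
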