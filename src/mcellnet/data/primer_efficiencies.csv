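gene,efficiency_percent
actb2,99.1
th,109.4
ddc,131.7
slc18a2,106.4
slc6a3,90.9
drd1b,104.2
drd2a,93.7
drd2b,93.6
drd3,92.1
vmat,106.4
dat,90.9
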