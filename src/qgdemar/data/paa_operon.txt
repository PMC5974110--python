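# paaABCDEFGHIJK operon (phenylacetate degradation); hosts the ectopic crp insertion
paaA
paaB
paaC
paaD
paaE
paaF
paaG
paaH
paaI
paaJ
paaK
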