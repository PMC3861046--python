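# DnaK (E. coli Hsp70, residues 4-603) subdomain ranges.
NBD-IA: 4-37, 112-182, 363-383
NBD-IB: 38-111
NBD-IIA: 183-227, 311-362
NBD-IIB: 228-310
linker: 384-393
SBD-beta: 394-502
SBD-alpha: 503-603
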