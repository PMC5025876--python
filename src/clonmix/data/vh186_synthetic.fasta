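>VH186.2-synthetic synthetic stand-in V gene; coordinate conventions of VH186.2 (codon 33 = TGG, FR3 ends YYC)
CAGGTTATAACGATGATTTTCAGAGAAACCAAGACACTGATGCTTGCATATCCGTCAGGG
TCAATGACGGTTAAACCCAAGCAAATCCGAACTGTCTGGATGAATTTAGCCATTAATCAC
AGGATACTGGTTCAAGCAGGAAAGCTACCGCACGCATCACCGGCCACTAGCCGGTCCCTG
TCAGTATGTTCCGTAATCGTCTTAGCAATAGCGAATAGGTGCGAAATCTCAGATTATGTA
AAAGGTCCTCCAACACCGGTAAGGGAGGTCGGGACCATCGATAATTATTACTGT
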