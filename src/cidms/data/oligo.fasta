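>ci_hth_doped_oligo uppercase=constant flanks, lowercase=doped region (177 nt, 59 codons)
CCATTAACACAAGAGCAGCTTGAGGACGCACGTCGCcttaaagcaatttatgaaaaaaag
aaaaatgaacttggcttatcccaggaatctgtcgcagacaagatggggatggggcagtca
ggcgttggtgctttatttaatggcatcaatgcattaaatgcttataacgccgcattgctt
gcaaaaattctcaaagttagcgttgaagaatttAGCCCTTCAATCGCCAGAGAAATCTAC
GAGATGTATG
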