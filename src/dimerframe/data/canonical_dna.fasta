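>widom601 Widom 601 nucleosome positioning sequence, 147 bp
CTGGAGAATCCCGGTGCCGAGGCCGCTCAATTGGTCGTAGACAGCTCTAGCACCGCTTAA
ACGCACGTACGCGCTGTCCCCCGCGTTTTAACCGCCAAGGGGATTACTCCCTAGTCTCCA
GGCACGTGTCAGATATATACATCCTGT
>alphasat147 reconstructed palindromic human alpha-satellite, 147 bp
ATCAATATCCACCTGCAGATTCTACCAAAAGTGTATTTGGAAACTGCTCCATCAAAAGGC
ATGTTCAGCTGGAATCCAGCTGAACATGCCTTTTGATGGAGCAGTTTCCAAATACACTTT
TGGTAGAATCTGCAGGTGGATATTGAT
>alphasat146 reconstructed palindromic human alpha-satellite, 146 bp
ATCAATATCCACCTGCAGATTCTACCAAAAGTGTATTTGGAAACTGCTCCATCAAAAGGC
ATGTTCAGCTGGAATCAGCTGAACATGCCTTTTGATGGAGCAGTTTCCAAATACACTTTT
GGTAGAATCTGCAGGTGGATATTGAT
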