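>synthetic_orf_1773bp synthetic reporter ORF (stand-in for CAN1; generated, not a natural sequence)
ATGCGCGTTGGCAGCAGCTCAGGTACCAGGAGAATGAGTGAGTCCCTTGATACCGTGAAG
GACGAATTTTGCCGGTACGATCACCAAAACATCTCCGGATATAAAATGAATAACAGACTG
TCCTCATCCGGAATGGGGAGGATAATGCGAGGCCCTGGGAGGATCGAAAAAATGAAGCGG
CACCCAAGACTGCTTAGATCGGTACCTGCTCCACGCGTACGCATTGGTCGGGAAGGAGAC
CGGGGTGAGCGGTCCTACTTACAAAGATCCAACGATTTCAGGTTATTGCAACGGGCGAAT
TGCCCTGCGGCAAGTCAAGGTGCCGTGTTGTGTGGGCCGTTTGGGCCCTGGGAGCTTAGA
ATGCCTGGGTCAGGACCAGCAGCCGCTCTCCTCCTTGAGAAACCGGAAAGTGGGGAAACA
AGTGACTCTTGGAATCGGCTCCAATGGTGCAGGTCTTCATATGTCCACCCCGCTACTCAG
GGAGCCCTTTTCGGTATAGGTCTTGGTCCATCAACCCGTGGGACAATCCACAATAGGGTC
TCCAGTAGAGTCGACGAGTTTCTTGTAGGGGAAACTATAGCCCACTCGAAACAGTCCGTC
GCTCTACATTCATGGCTTTGGTGCCCTCAATTGACGCGTGTAAGAGAACCTATTTGGAGT
CCCTTGACCGCTGGGCAGGCGTCTGGAAGATTGGTCTTCTGCAACGGAATGGTACGTGTC
TGCTGCCATATGGATAAATCTGCTCATTCAGTGACTGTTGTAAGCGAAGAACATGAATGG
GCTCGAGGTGTGCACGCTGGGGTGGTTAACAACGGGCGGAAAAAGAAAGTATTGCTAAGT
CCGCTCTATACAACGTTACCCCGAAACGTGGAGGGGCGACGGCTCGGAAGAAGTTCACAG
AATCTACAATCCCGCTTTTCATTTTGCGCGACAGGCTGCTATAACCCACTTGCCGCAATG
TGGGCTACGTCCAGAAATAGGACAAGCTTATTCCCGGGAGACCTCACCACGCCTGCGCCT
GGTTTTAAACTAAAGCACCCATCGCTTGCCAACAGGGCATTAATGACATCACAGCCTGAG
CGGCATCTTGTCTCGATGGCTGGAAACAGAGGTCGCCGTGCGTTAGATCCGGTACCAGAG
ATACCTCGGCGCCGTCGGAAGTTCGAAGAGAAAGATCCACTTCCCATTTGCCCTACCATA
GTACTTCAACACCTACGCCACTGCTCTCAATATGGGGCTCTAACGATTCATCTTTTGGGA
GTGACTAGACAGCAATACTCATTCACGCCGTATGTACTGAGTCCCATGAAATCTTACCGG
CCCTTCCTCAACAATGTGGCGTTACTGCAATGTTTTCGAGAAGGCCTCTTACATGAACCG
AAGCTATACACAATACAAACTCTAACATGTGAATATCCAGTGCATTTCGGTAAATATCGA
AACAATACCAGGGCCTCAATCTGTATAGTGTTTCAGCACCCTGGCGGGAGGATCGCGCCA
TATGAATCTGATCTTCGGATTGTCTTTCCGTTTGTATTACAATCATCTAGAGACCGTGCG
TGGCAGAATTTCCTGGAGGTGCTGCCTCTCACGACGTGTGCCAGGTTGCGTGCTCGACCA
GATTTGAAGGCTGATCAAGGCTATAACCGAATCATCGACTCCCATAATGTGTTCGCGGCT
TCAGCAATAGAGGCTAGCCTACCCGGACCATCTGAGCAAACGGCATTCGCCGGGATACAT
ATTATCATCGTCATGCAGGGATCGGCGGTATAA
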