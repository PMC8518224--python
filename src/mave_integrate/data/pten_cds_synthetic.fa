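>pten_cds_synthetic synthetic stand-in CDS (403 codons + stop); catalytic-motif and named-panel codons fixed, remainder random sense codons
ATGGAGGGGGCATTCATTCGTGGACTATCGGGCCGACCTGGAATATATTGCTTACGGGGT
ATCAAAGAAGATCCTTCAAGGGCCCCTTACGATATGCTCCGATCGAACATGCCTGCCGCT
TTCATCTTGGCCGCTTACAGACAAATTCTGGATGGTATGTTTGCACTCTATTTACTCACC
GATCGCCCATACTTTGGAAGTCGTCGCCCGAGGATTCCTTTTCTTATCGGCCGGCGCGAT
CGTTCTAGTTGTCAGCGTCATGGTCTTCTCGAAGACGATCTTGAGTGTGACATACCGGGC
GTTGTCAAATGCGAAGCGGATACCCTACACGCACATAGCGCCAGCCTGCGAGGAGCCGTA
GGCAGTGAATGTGGGCAGGTGATAGGACGAGTAGGGTTGACACCTCTCTACGCGCTAAGG
TCACCGGATCATGTTAAACCCGACATTCTGCACTTTTCCGACGTGCAACTCGTTCGTACT
ACCGAGTGCAGAGCTTCAACGCACGACGGTAGATCGCGTGACGTAGATGGAGGGTCTGCA
AACAGCGAGGGGGCCCCACGGTCGCCAATCAGTTTAGGACCCCTTGAGGTGAGCACAGGC
GCTAGCCTATTTAATCAAGACAGCGATAGGAGCAGAGAGGGGACCGCTCCTAACTGTGAC
ATACAAGTGGGCAAATCGACATGCTTATGTACGAGATACGTAAGTAATACAGAGGAGACT
CAGCCGGATGGACGTACTTTTCTTAGAAGTCTTGATCAACTGTGCACTTGTGTAGCTATG
TGGGTTTGGTCTAGAGGTCCTCTGTCATCGGTCCAGGGAAGCGATCAGTATCCTCGTTCG
ATCGTCAACCCCCGGGGGATCCCTCGTACAGTGAACCATGGTTACGTTAGGGCTCCTGTC
GGGACGATACCTCGATCAGGCTTGTTACGAGGTACTGATAAACGTCGGTACACTAAAGGT
AGTTATCGTAACTTAGATTCCCTAGAAAGGACGCTCACTAGGAGCTCCATCGGCAAGTTG
CTGCCCCTTAGCCTATGTAGTTGTAAGAGGCATTATATATGCCCCCTGCTAGCTGGTGAA
GTGCCCACAGTGTCACCATTGTATTGGAGTGTTCTTACCGTAGTCATAACGCCGATCCGC
GGGTACTGCGCGATGACACATCTGAGAGTCGAGGTCCTCTTAAATAGTTTCCAAAATGAT
GCCGATCAATGA
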