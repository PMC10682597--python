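>mini_virus_0000|synthetic
ATGGAAGGCAGCTACGACTGCGAGCACGAGAACCCGTGCAATGCCAAGTACAGTAACGGAGAGATAGGCA
CCGAATTCAGCTTTTTCTGTAAGTTCGTGGGCCGAAAAAAATACGTGTGCTTTGAAGTCCTCCACACGCA
CCAGTTCGCGCAGCACCACTTCTTCAATCACATAGAGCTGAACATCATCGTAGCGGGACTAAACTAA
>mini_virus_0001|synthetic
ATGCACAACGTGTTTGATGACTGCGACGAGTACACCGACTCCGCGCCGGGCCACTTCAATGTGAGCAGTT
TATACACGCCTGTTTGCGAGGTCGAATGCATTCAGAACTTGAGGACAGCCGTGAACACCAAGGGTGACAG
GGATACTGAGTGCCAGTTGGAGGCGGGGACGCACCGATACTCGTACAAGTACGAGGAACAGTACCCCAAC
ACGTTCACATGCGAGTCTAATACCCACGCCAATTAA
>mini_virus_0002|synthetic
ATGGCCAATTTTGTGCCGGTATCTATAGTATACTTTATCTGTAAGAAAAAGGATTTACACATCAGACTGG
CCATCGTGGGAGACGCGAACGAGGGCAGCGTATTCGAAGGGTACGCTCGGTATCACGAGACGGACCGGTA
CCACTGCTTGAGGAAGCATATCCAGTTCCTGGATCGTCAAGAGTTTGGCGGAGGCCGCGCAGAGCCTTAA
>mini_virus_0003|synthetic
ATGGACCAAATTAGACCAATTAAATGCAGGGGGTACACTGATTACCATCAAGTGGAGTTTGTCAACATAC
TTCAGGGCGCCTTTGTCCACTTCCACCTGTACCCCTGCACTCCCCTGTGCGAGCCCTTTTCGGAGCGGCA
AGGGCTGGTGTTTAGCAATTTCAAGGAGCTGAATTCCCAGTGCCGCGGCTTCGTGGTCGGGGAGAAGCAC
TATTTTACTAAGCCGTATTTGAGGTCCACCAAGCGGTAA
>mini_virus_0004|synthetic
ATGGACCCGAAAGGGCCCCAGGACTCGATACAGGGACAATGCGTGAACACTGACGGGCGGTGCAGCATCG
GAGAGGCGTCGGTGCTCCAGTCGGAGTTGATTTTCGAGCAGCCCTCCACCTGCTACTCAAACGCTAGCTT
TACCCAGATCGCTAATCAGGTCTGCCCTGATACCGAACTCCAGGACTCAGAGATAGCTTTCCCCCGGCAG
TAA
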