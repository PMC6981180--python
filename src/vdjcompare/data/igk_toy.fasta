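>TOY00001|IGKV1-5*01|synthetic|F|synthetic toy germline
CGGTACCATGTCCTAGAACCGGACTTCACGTAGTTCAAAAGTTGCGGTCGCATACGCCTT
GTGGAACATGCAGTTTGTAGCTTAACGACGAGACCAATTGTTCCTTAATGAGTGACAATC
TGTCAGCAGTATAATAGTTATCCT
>TOY00002|IGKV1-33*01|synthetic|F|synthetic toy germline
TAAGCTAGGGCATGAACTAACTTTCGATTACTTGAACAGTCCTGTCTCGCCCTTGCTAGT
TTACGGCCCCGACGGAGATAGAGTCACTTTATAAACTACCGTTGCCTCAACACCCCCATT
TGTCAGCAGTATAATAGTTATCCT
>TOY00003|IGKV1-39*01|synthetic|F|synthetic toy germline
GACCTCGTCACTCCCAGACGGTTTTGCGCAAAAGAGGACTAGGTGACCTTGCTCATCCCC
GCACCAGTACCTTGCTCACTGTTGGTTGACTCGTATGCTGAGGATCGATCGTGCACACAG
TGTCAGCAGTATAATAGTTATCCT
>TOY00004|IGKV2-28*01|synthetic|F|synthetic toy germline
CAGGAACTGCCACTGACGAGCAGGTGGGAAAAAAGAATGTATCTCGACCGTTAGTATAAT
TGTGCAAGTTTTGGGGATCTAAAAAACCTCTACGAGTCATCTCACGGCCCTCACTACCTG
TGTCAGCAGTATAATAGTTATCCT
>TOY00005|IGKV2-30*01|synthetic|F|synthetic toy germline
ATTCGTGTGTATATTTTGGTGGTTATCAGGAAGACTGGTTAGGATGAATTTTGTACCAGC
ACGGGTGCGGTCATTCGGATGAGAGCTCGGGATAGTTAATAGACCTTGTAAGTCTTGAAC
TGTCAGCAGTATAATAGTTATCCT
>TOY00006|IGKV3-11*01|synthetic|F|synthetic toy germline
TATGATCGTGCGCCAACAACGGAGAAGCTCCGTGGCAATTTAGTGTCTATTAATCTTACC
ACATGACGGGTCACTCACAGAGTCCTAGTTAATGAGGGCAGGGATTTCCACAGAAGGCAA
TGTCAGCAGTATAATAGTTATCCT
>TOY00007|IGKV3-15*01|synthetic|F|synthetic toy germline
ACAACGTTTCTAAAAGCTAATTTATAACCGAAGTGGACCGTTTCGCGTGTTACTTCTTCC
ATGCGGGCACAATATAGGGTTAGCTCTCGCACCAGCCAACTTCTCAGTAAAAATTTGAAC
TGTCAGCAGTATAATAGTTATCCT
>TOY00008|IGKV3-20*01|synthetic|F|synthetic toy germline
GAATTCCTGCACGCTTATACACGTACTCTTTACGATAGGTATAAAATCATGTCTGGATTT
AATTAGTGCTGTTCGTTTCCGTGGTGCTTTGAGGGTTCCGATTTCACGCAACACGAATAC
TGTCAGCAGTATAATAGTTATCCT
>TOY00009|IGKV4-1*01|synthetic|F|synthetic toy germline
CAGAGCGAGTCCGTAGGTCTATCCCCGTGTGCCAGTCGTTAACAGCATAGCGGATACGGC
AAGAAAGTAATAACTCAAGGATGTAATGGGCCTCCCGTAGTTCTTGTTAGTGTGTTGAAC
TGTCAGCAGTATAATAGTTATCCT
>TOY00010|IGKV1D-8*01|synthetic|F|synthetic toy germline
CCCTGGGTCTAGGGTCACAAGACAGTCATTTGCCCTCCGTCCTAGACGTCTTTCGCGGCA
GGCCTGCTCACGGCGCTCAACAATGGAGCGTTTGTCCCCCGGTCCTCAACTACGCTCAGC
TGTCAGCAGTATAATAGTTATCCT
>TOY00011|IGKJ1*01|synthetic|F|synthetic toy germline
CAGGTACTTCGGCCAAGGGACCAAGGTGGAAATCAAAC
>TOY00012|IGKJ2*01|synthetic|F|synthetic toy germline
TGGTATCTTTCGGCCAAGGGACCAAGGTGGAAATCAAAC
>TOY00013|IGKJ3*01|synthetic|F|synthetic toy germline
AAAGGGTTCGGCCAAGGGACCAAGGTGGAAATCAAAC
>TOY00014|IGKJ4*01|synthetic|F|synthetic toy germline
ACAGTTTTTCGGCCAAGGGACCAAGGTGGAAATCAAAC
>TOY00015|IGKJ5*01|synthetic|F|synthetic toy germline
GGACACCTTTCGGCCAAGGGACCAAGGTGGAAATCAAAC
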