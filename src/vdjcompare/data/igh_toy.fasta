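>TOY00001|IGHV1-2*01|synthetic|F|synthetic toy germline
ACAATTCACAATAACTGTTGTGTTCCCTTTAAGACTTAGAGGGTGTCTGGAGGATGCCTA
CAAACCATCTTTAGAGTATGTCCCGGTTACCACGGTCAAAGTCATCTCCCAAGGCGCCGA
CTACTGGCCGTTCCGCTGTGCGAGAGA
>TOY00002|IGHV1-69*01|synthetic|F|synthetic toy germline
GACCAGTCCGTAAGCATCCTCGTAACTTTATCCACTATTCAGAGAGGTCGACACAATCGA
GTAGAACGTTCGCGCGGTGAGACCGTTCGGTCAGAACAATGTCCTCATGTAGACCCCGTA
CCGTCATCTTCGGTAATGTGCGAGAGA
>TOY00003|IGHV2-5*01|synthetic|F|synthetic toy germline
GAGTGGGGCGGCCCTATACCACGAGAGCTGCCAGACCCTAGCTTACGAATTCTCTTATAT
TGCTGGATTATGACCAAGTGCTCAGTAACCCTATCTCAATCACTGTGGATAGAAAATTTT
TCTGATCCGCACGTCGTGTGCGAGAGA
>TOY00004|IGHV3-7*01|synthetic|F|synthetic toy germline
AAGTATGACGCAGCAAGAGTCCATAAGTATTAGTACACGCCGGAACTTTCGTCCGCCTCC
CCCGCGGTTAGCGCGGCTAGATTTCGAGGCACCGTGAGGCGACTAGCATCCATCACCAAG
GAACCCGTAGAAATCTTGTGCGAGAGA
>TOY00005|IGHV3-23*01|synthetic|F|synthetic toy germline
GCTTGGCTATTGCTTAACTGAGCAATTTTTTAATAATTAAGATAGAGCGAGAGGCTTCGC
CCATTCCGCTCAGGTAAAACAGCTTGGGATGCAGACGATCTGTAATGAAAATGCGATACG
ATAGCTCGATGCGCGTTGTGCGAGAGA
>TOY00006|IGHV3-30*01|synthetic|F|synthetic toy germline
CACCGCGCTTCGCTCTTATGACGATACATCGTGCCCCGGGACGAGCCTAATTGGGTCGCT
GCGTACCCGGTTATTTTATTGACTGGTCTCTATCAAGTGATTTTTAAGTATCTCACGATG
AATAGATTGAGTTTATTGTGCGAGAGA
>TOY00007|IGHV4-34*01|synthetic|F|synthetic toy germline
CAGGCCCCGATTGGCGTAAAATCCCTTATCTCGACTCCAAGGGTATGTATATTGCGGCCA
CTTGAAATAAGGGGTAGCTCCCGCCCTGCACCTCGATCCTGCAGTCAGCATTACAATCTC
ATTACCGTGACAACCCTGTGCGAGAGA
>TOY00008|IGHV4-39*01|synthetic|F|synthetic toy germline
GCCCTGCCTCGATCAGATCGCTTCAGCGTCGAGCTCGAAGCCGGACTGTTTGTGCCATGT
TCCTAGCGAAACTCGAATATGTTCTATTGCGGGGGCGAGTAGCTGTACCAATGGATTAGT
TATTTGATAACCTTAGTGTGCGAGAGA
>TOY00009|IGHV4-59*01|synthetic|F|synthetic toy germline
CGATGTTCGTAACCGCGCCCGGAGCTGTCAGGATAGCGTGCGGTGTGCGCTCATCTCGGT
GTACAGAGGGAGCGATGTAATTGCTTATGTCAAACCTGCTGTAGTTTCGCCGATCTTAGA
GCTGAAGCAGAACGCATGTGCGAGAGA
>TOY00010|IGHV5-51*01|synthetic|F|synthetic toy germline
GAAGTTACATTTCCGTTCCTCGCGACGTCGGCCCGGGCACACCTTTATACGTCAAACACC
TGGAACGGAGATGAGGTTACAACCATCGAGCGGTATCACCCCAGCGGTGCTAGTTAGCCA
CATGATGTGTGATGCGTGTGCGAGAGA
>TOY00011|IGHV6-1*01|synthetic|F|synthetic toy germline
CTACCTCCTCAATGCGAGGATCAATGTTGTTCAAAATTGCGGGAACGGGGGTTGTACGAT
TAACGTTACGAAGCATGGTTTTCGCTAAACACGCGAGCGAGACATAATGCAATCCTAACT
CAATTTCGGTAATGTCTGTGCGAGAGA
>TOY00012|IGHV7-4-1*01|synthetic|F|synthetic toy germline
GCACACCACTTTTGTGAATTGGGGACGAAGTTCTCCTGGATTGCTTCTTGTTTTCGGAAT
CGTTATTGGGTCTGAGCTCCCTTAGCAGTATTACTTAGAAGTGATTGCTGAATCCTCGTC
ACATTTGACCGATGGCTGTGCGAGAGA
>TOY00013|IGHD1-1*01|synthetic|F|synthetic toy germline
CTGCGATCAATG
>TOY00014|IGHD2-2*01|synthetic|F|synthetic toy germline
GCATCCATATCTGCCTTCAAC
>TOY00015|IGHD3-3*01|synthetic|F|synthetic toy germline
ACTCCGAACTAGCTACGGGCGATGCGTCTCA
>TOY00016|IGHD3-10*01|synthetic|F|synthetic toy germline
TCTCGGATGTCAAATCCTAGGGCTCCACGAT
>TOY00017|IGHD3-22*01|synthetic|F|synthetic toy germline
GAAGATCTCAAGTGAGTACGGCCCCACT
>TOY00018|IGHD4-17*01|synthetic|F|synthetic toy germline
CCCTGCTAACCATCAT
>TOY00019|IGHD5-12*01|synthetic|F|synthetic toy germline
CGCAGTCTCCGCGGCTAT
>TOY00020|IGHD6-19*01|synthetic|F|synthetic toy germline
CACGGGTCACAC
>TOY00021|IGHD7-27*01|synthetic|F|synthetic toy germline
TGTTTAATTTG
>TOY00022|IGHJ1*01|synthetic|F|synthetic toy germline
TGGCCTGTTTGGGGCCAGGGCACCCTGGTCACCGTCTCCTCAG
>TOY00023|IGHJ2*01|synthetic|F|synthetic toy germline
CGTAATGTCGTGGGGCCAGGGCACCCTGGTCACCGTCTCCTCAG
>TOY00024|IGHJ3*01|synthetic|F|synthetic toy germline
GCGTAGTATCATGGGGCCAGGGCACCCTGGTCACCGTCTCCTCAG
>TOY00025|IGHJ4*01|synthetic|F|synthetic toy germline
ACCTGCTGCTGGGGCCAGGGCACCCTGGTCACCGTCTCCTCAG
>TOY00026|IGHJ5*01|synthetic|F|synthetic toy germline
TCAAAATGTGTTGGGGCCAGGGCACCCTGGTCACCGTCTCCTCAG
>TOY00027|IGHJ6*01|synthetic|F|synthetic toy germline
GAGAATGCCTTATACCTTGCATGGGGCCAGGGCACCCTGGTCACCGTCTCCTCAG
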