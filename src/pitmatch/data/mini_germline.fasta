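>TRAV1-2*01
AATATGCAGGATGTCCACAACCACAAAGCTCAAGCTGATCAACCCTTCGACTACCAGCTCCAGGCGGTTACTGGGGTACCTAGGCAGTTCGCCTCTTTGGGTCGTAAATTACCGCACATGTCGTATATATTCCATCAAACAATGCGAGATGAAAATAGTTTGCCTCGTAGTTTGTCCATGCATATGCGAAACCTGTGTCCTGCCATTGGA
>TRAV5*01
ACGAGACAGAGGATGCCCTCTGTGGTTCATATAATTGGTCAGTATCATCAAATGACCCATGGAGCGAGACAAGGACGCCCGCCCAGTGCTAACCCTCCAAACATCGCAACGATTGTTAAAGTGGAGCAGTTAGACGATTTCCTCCCTCCTATGTTCCATGCAAACCCTAACGCTGAACCCACACGCCTGATGATGCGACCGTGTTGGCGGAAGGGC
>TRAV8-2*01
CAGTTCATAAAATACAGTATCCATCCATACGGCCTAAATGTGATGCGTCGTTTTTCTCAAGCCATTAAGCCCCTCAATCCTTATCCTTTTGCATATTTCTTTGCAATGAGGGACATAACAGATATGTACTACAACGCGGGGCACCCTATGTACAATACTACTCGAGACCTTCGGCAAAAGGGATATCTATTCGACCGGACGGAAAAATGTACGGCTTCACCT
>TRAV12-2*01
CCAATTATACCGATGGTAGCAAACCAGCTTATGTTTCAGGACAACGAGCCAACCAAGAGAATAATTCAAAGTTTGCACTATTCCTACGTACGTATGGGAAACGATCACCGAATGAAGTTCATGAACGCTCAAGACGATGACAATGAAGGGATGATGGAAAATGAGGATTACCGGCGAAAGATAATGGAACATTGTGTCGAACACGTT
>TRAV13-1*01
GGGATCGTCTCCTCTCATGATGAACACTTAGCGGTCGGCTCCGCCGGGCAGGACCATTCGTTCCAAGTCGAGGCGATGGCTACTGAAAGAGTCGCGGACCGGGATAGGCACCGTTCAATCCAGTCACGGTATCTTAACACATCTGTTAATAGCAAGAAAGGAGGAAAAGTACATAGAATGGCACACGTCAATGTAGGATGTGCCTCAGAGGGC
>TRAV26-2*01
TATTTCATCTCTGAGCATCAGCTAGCTATGAGATTCTCCGAAGTCGAGCGTGACAATCACGCGTCTTCGGTCATCTATCGCATGGAAAACTATAAGATCGTGGGGCACGTCCATGGAGCAGAGGAGGCTCATACGCACGGTGGTTATCTACATAATAATATGGAATCCGCTGAACCCCGTCGCGAAGAGTCCCAGATAGAATACTGTTCTGGGAAGTTG
>TRAV4*01
TATCAGGGCTTCAAGGCTACTGACGGCATGGAAGAGCCGTATCTGGGATCGACTACGTACGCTATCAGAGACCCCGGACTCGAAAAATTTCAAAGCGTAAACGTTCAAGTCGGTCTCATAGACGCTAATACTGCTCGCAACGCACTTTTTGCAAAGATGACGCTTCAGCTAAAAAAAGAGAAGCAATTCGAGACTAGTGGGCTCCCTTGTATTCGGATATGG
>TRAV41*01
GCCTCGGTGATTGCTCGTCAAATGCAGTTTACCAGAGGGTTGCCGCACATGCAAATGCAGAGAATTGCGTTCTCGGGTGAGCCTTACCATTTGCTTAAGATCACAACATTCGGACCACTATATACCTTCCATGTGACCTTTGCCATGAATTATACCATGGGTCGTCTCACCATGAGCCACAAGCTCAGCATATATTGTTCCCCCTGCCTA
>TRAJ8*01
TGGGCGAGTCCTACACAAAAGCCACCCTTCGATAAGGGTTTCCTAGCCCCGATGAAC
>TRAJ15*01
CGCAAACTCGCACGGCGAACCGGCCCATTCCAGCATAAGCGTCCCCTACTGCTGGAT
>TRAJ36*01
GCATCCCCGCGTCGACGCCGTTCGTCCTTCTTGGGTCATATGTTAAATCATTTAGTA
>TRAJ44*01
CATTGTACAAAGGCTACTACGCCACCATTCAAAATCATGAAAATGTACTTCGATGTT
>TRAJ49*01
CTTTCGGGCGCTACTGGTCCTACAAGTTTCAAATTTCCGTATGTACGACAGAATTTT
>TRAJ53*01
TTGCATCGCACTCGGCTGTCCTACCTGTTCGGCAGTCGAGTCAAACAGCACGCTTCG
>TRBJ1-1*01
CAACTACCAGTTGCCTTGGGCTTCGGATTCCATATCGATCAGCACCAAAGCCAAATC
>TRBJ1-2*01
CGCCAGCGTCAGCCATTTGCTCTTTGGTTCTCGTATAAAGTCACGCACGAGGACTAT
>TRBJ2-1*01
CGGGATCGTCGCTGTTTCGGAGCCATGTTCGAGAGGAAACCCAGTAAAACGCATGAA
>TRBJ2-3*01
CGGGATGGCGTTACTTTCTTCCATCTATTCATTTTCAAGAAGCCGCTCTATTTCATT
>TRBJ2-5*01
AAGGGCCCTCCCCTCCAAAAAGCTTACTTCCAGTATCATAACTCTTATATCCCGTTC
>TRBJ2-7*01
CTACTCCCATGCGTTACTCGGTCGTCTTTCGTAGTTAATATGCCCCTGGTTCACATA
>TRBV5-1*01
GATCGATATATGAAAATGTCTCCACTCATGGATCGCGCAAATAATCAAACTGTTAGCACATATGGGGCATTCAGTCACATGCAGTCCGCAGATTTTATGCTTCCCGCGGTCCCCGAAGCACTAGGAGTGATGAGAGGAATGCCTGCTGATGACTTGCACCGCGATCAGCACGAGCATATCGAAGCACACGTCAACTGTAACAAAATGG
>TRBV7-2*01
GACCAAGTTCAAATCCAGGAGGTAACCCCTAAAGTTTACAACACCACAGATGTCAGCTCCCAATCGTTTCTGAATTTTCGTTTCGTTTATCCCGGACATCAACATGTCAGTGACAAACGCATTTTGGTGCAACCAGCACGCATAGACCGGATGGACAACCAGAATATACGCGAAGGTTACAAAGTCACTACGAGTTGTCATTTCCATC
>TRBV9*01
GCCATGATTGAGGCCAATCACTATATAGACCTCCAAGACATGGCCACTGCCATGCATGAGATGAAGACCAACTTTGTGAACGTAGAATTGCACTCTGACCGTCCGGATTATCGTATGCTATTAAAACTTCGGATGAATTTGTACCCAAAGAAAGAAGATTCAGACACGCAGGATTTCTTAGACAACTTTGAACGGTGTCTTTCACTCG
>TRBV12-4*01
ATTTCCTTGCAAGCTAGTATATTTAATCACATCGTCAAGAGGTTGGGCTCGCTACATACCGTCGACTACGACCGCTTTGTTACCGCCCGAAATTTTCAGTTTTTTTCCATTAAGGGAGAAAAGATAACGAAGGGTGGCGGGTCCAGGGGGCTGACGGGATACCAGCTTGTTTTTGCGTTGGAAGTTTTTATAGGCTGTTTACCTATCA
>TRBV19*01
CAAATAAGAATAAAAAACGGCCGCGCGGGTTACACGTCTTCTGCTCGGGAGCGAGTCAACGGGATTCCTATTATGATGGGTTCGCTTTTCTATGCGAATGCCGGCGACATGAAGGTCTTCTCACCAAATCTGTTGGACTACTCACAAGGTTCCGAACAGATGTTTGCTGCCCTGTCGAGTATGGACGATCCAGGATGTACACCAGCGG
>TRBV28*01
GAAGTCTATGAGGCCCAAGAGATGGAGGAGTTACAGACCCCTCGGATCCTACAGTCTGGTCAGTACAGCCTCGACTTTACTTACACACGCAAAGACGCGTCGCGAGAAACCATCATGTATATCCAATTGACCGGCAACAATTATAAGCCGCCGACAGTACGTGAGGTTTTTGCGGCGACGATGCGCCCGGTCGCTTGTGCCCGCCACG
>TRBD1*01
GTGCATGGACGA
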