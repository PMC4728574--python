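>pseudo_phiX synthetic 5386 bp circular control; randomly generated stand-in for the phiX sequencing spike
CAGCTAATATGTAGTCATACTCGTGCCTATGGCTCGCTACGCCCCCATGCTCTTCATGCAATAAACCATT
CGAGACAGAGAAGCGAAACATTTACGTCGTGTTTGGATAAATATCGGCGCCCGACAGGCAGCGTCTTGAT
AATGTTCGAGTCTACAGTGCCTAGGGAAAGATCCGTCTGTGCTCACTTGGCTGACCGGTGAAAGTGCTAA
GGCAACCCCCACGGAAGGATCCAACTTCACAGGCCAAGGGTAGATTCACCATCATTGTGATGTCAGTGAT
AAGCGATAAGCCAGGGTGGTTCACGCCATTGTTACGATGTTCGTGCGAGCCTACTGACGGCAACAGCCCC
TTGGTGGTCTGGCTAAACCTTCGGACGTCTTGAGTAAACTTTCCCGATGTCGAGCCGCAGCTTGCAGGAG
CGTAAAGACACTCGGAACTCCCTACCCCTTAACTCCATCTTCCCGGTCGTTGGGGATTGTTTTTAGACTC
TACCGACACAGGTGGTTCGTGGATGGAGCCCTACGCGCGTAATGTTGTCTGCATAGGCCACTGATGGACA
TTCATAGGCACTCAAACTCAGATGGAGACGGTTCAGAGCGTACATCCTCCCGAAGTATCTGTGAAGGTCC
ATGGCCGCCAACTGTCGCGCGAAGCAATGTGAGCTTGAGAGAGTGACATGTTTCCAACTTATTGCTTCGA
CTGCCTCTGTTCCGTTGAACACACTGGGAGTCGCTTGGTGGAGTACATAGCAGATAACGTATACATATAT
TACATTTAGAGTCCTACGTACTAGCCCGCGGCACTTCGGATTTAAACGGAACCTAACCGGCAGGGATTTG
AGGATTAAGATACGGGTAGCTCCCAGTAGAAGGATCGCCAAATTTAGAACAAAGTGTAACATAACAGCTC
CAAAACCGTCGGGAGGCAGAAAGTACGCGCTATTTATCATAGTCCGCTTGGCTAATGCGCGTAACCAATT
CGCCCGTGGTCTCCTAAATAGCTATCGGGGATGGTTAACAGCGCGCACGAGGGGCACTGTCGTTAAAGCT
ATAGTAACCATCAGACGTCCAGTCGGATTGAGGCAGACTCGGCTTCGAATCGCGCATATACGATCGAACA
TCGGCAAGACACAACCTTGGCGTATGTTGTGAGTGGTGGCGATCTACTACTCGTGATCGTACCCGACCAC
CGTCCTGGTTTCATCTAACGTCAACTGTCTATGCCCCGTTCGTTGCTATGGCGCAAGCTCCAGTCGGCCC
CCCTACGTGTCGTCACTTTCTCGGCCCAAGGTATACACTAGAACTGTGGGATCTTGGCCGTCCGGAGTTG
TGATTAGCCAACCGACGAATCACGGAGAGGGGACCGGAACGCTGTCGTTGAACCTTGATTAGAGCATTAC
CTAAACAGAGGGAAGCGCTATATCGCGAATCCTTGTCCCGACCCGCACACCTAAATTGCGCTCCCCTGGC
CACCGGATGCATATGCATTTATGGGCGTACGTGTACATCCCCTGTGGTACGCCAGCCCTGATACCGGGGT
TAGTAGCCTAGTGTTGCGACCTTTTGGATTAAACGGCTGCCCGTTTCCCGTCAAGACTGCAGGATGTCAT
TACCGACATGTGTCCCACCTGAACGCAACTGGTCAGTGGTGGTGGTGTCGGCGTCCCTTTCCTGTGCGCT
AGCTGCCCTGCTCTTTATGACCAGGGCGCCGCATCTTGGAACATTCTGTGGATCGGCCCGAGCTTTTTAT
AGGCACCTCGCACAGACTAAGTTGGCAATGGCCACAAGTAGCTACTCCCCGGGACTATTACTGCTTTGTT
TGAACGTGGAACTTTCCAAGAGCACAGCCTGCTGGGGTATAGATCAGTGGGAAAATCCCCTGTTAATAAC
GTCTAAGATCGCTCAGCGGCACCGCCTGCTGCACAGGCACGCTATGAATGGTGACCGCATTCTCGACACT
AGCGAAGGCCGGAGAATCTTCATATGTTCGGGTTAGCAGGTTTAGGATGGGTATTCCCAATGATTGCGCA
CAGCGCTGCAGCTGCCTACGGGCGAGTCTCATCCGTCCCCTGCCAAGATCCTAAGTGATGAGATATCATT
ATAACTCATTTCTCGAGTGGGGGCGGCACATATAAGTCAGGCAAAAAAGGCATGGGAAGTGAATTGATAT
CTGTTCATCATGTCTCCCCTAGGCTGTGCCGGCGACACCGCGCCTCTGATAAAGAACCACACGGCCCCTG
AGTGAAACGGTATATCCTGACGATAAGGATTCGTTTCCGGTGCAGAGTTTGACAGCACCGGACTCAATGA
GGCGCCAATTACCCGGGGCATGAGTACATCAATGACGCGGGGGATTGATGAAGTGGGTAGCACCAGATCA
TCGAGAGCTCCCGTACTCAGATACCTCGAAGGGCGTATTCAACGTTTGTGGGGCCATAATAGCTGCGCTA
CCAGCGATGATTTGCCGCTCACCTATCTTATTTCGCGTGCACGATAAGTAGGATATGCGCCCACGTGAGA
GGCCTTGGGAAGAGTAGTACGGCTTATACACGGATCGAAAAAGTAGCCGCGAAGCATCAAGTATCTGAGA
TAGGAGAGGCGGTAGTCAAAAGCGGTAGCATAGTCACAAAAAACACGTCTTATGTCCTTATTCCACTAGA
ACCACATTCTATGCCGACGTTGAAGTTCACTCCTCGACTGCAGATGTTGTGTGCGTGCCTGTAGACTCTT
TAACATGTCAGGCTGACCGCCCTCACTGGGCATGATGATGTAGCAAACATTTGCGGATTGCGTGGTCTGT
ATAGGAAATGCTTCTCACTGTCCCTTAGTAGGTCCAAGCAGCGCGGTCAAACACCCTACATGCCCCCCCG
AATCCTCGTTACAATAGGCGTACTTACCGGCCCAGCATCCCACATGAAGCTGTTAAACGCCACTTATATG
CTGCAAGTGTACGCCGGTGGGGATCTGGCAGCATGACTCGTACTGACTACATCGTCAGAAACGAGCTACC
ATCACGATTTTCTGTTGATTCTATGCCAGCCCTTAAGATAGGTGCCCTTTGCCAAGTTGCCTTCACATCG
AAAAATGTACGGTAGCTACTTAATAAGGACCTTCGGTTGGACGAATCACTCGGTTGCGAGTCGCACTCTA
CTCCGGCCCTATGCCTGGATGAGGTCGTCTAAGATTGATGCAGTACATGTTGTAGCAGTGTGCGCAGACA
GACAAACCGTGCGCTAGCTTGGACATTCTCACTCTAAAAGTGCGAAGAAAGAATTGGACAGCAATCTGCT
TCCTATTACTGCTCTAACTTGATCCCCTGTACTCTCAACAGTGACCCTGTGCCCACTCTTATATTACATA
GTCGACTATGCAAGACCCCGTAGATGCATACAACAGCGACGCCGGGGGCGAATAACAACACTATACAAAG
CCCCTTCGACACAAGAGCAGCTATTTCTCTGCTCTCCGGGCTAGATCTGCTACTAATTGTGGGAAGATAC
ACCCCATGTTTCAGGTTATGTAAGCACTGGAACGTGCATAACTCTATTCCTGTGGCGTCGAACCCAAAAG
TCGGCCAGGCCGTTCTGGGAACTGTCCGGGGGCCAATGTAGAACTATACTTCGATGAGAGTTCTGCATTC
CGACCGTAAACGTTTATTCCGACAAGTGGTAATATACTGGAGAGGTACATAAGGCGCATGGTGAGAAGAG
TCTGGCCCGAGATCTAAACAAATTCGAATGCGTGCCGAGCTGGCTTAAGAGCTCTGTCTTACGCGGTGGT
CGCAAGTTCCTGTGGCGCCGCCAGTTATCGATCCCTGTGGCTACTATCGACAGAATACCAGACAACTGAG
GAGAGACCCTTTTGGGCCCATACAACCGGAGTCGTGCTAGGTACAGGTAACCCAGATTGAGTTGTGGCCC
TCCGAGTCAGACCGTGAACTTATGTAACGTGTTGAGGGAATGAACTAGTGCGTGGTCTGTGATCCAGCGT
AGCTGTTGCCGGGATAAATCGCCACACAGCGTCAACTCTGACTTTCGTCGTCGCTCCCGCTGAACGTCCG
GCCTATAAATCTCTGTTCTACGGGAAGCGCGGGTATTAAAATATGTAATGACGGGTGCCCGGAAGTCCTT
GCCATTATTGGGTCAGGCAGGCACCATCTTGTCGACAGCCAGACTGACAGAGGGAAGTTTTCCGTAGTGC
TCGGTTGTGTATTCCCATTGCATCAGTTACCCGAGCGCTTGTGGCAAGCATGAACCGGGCTTGTTATTCG
TATCAGCTGTCACATGACCTATCGGTCGACGGCAGGCTGCTTGTCGCTGGCGGAGAGCGATAACCACCTG
GTGACCGCCCCACGCGTCGTTAGCCGCGTTTATCCACCATCTAGCTGATACTATCCGTCATGACATTGTA
GTGGTTGTATCTATTTAAGGGAGCAGGCTACAAACAGGCCGCCCAGATGCACAAACAAAGAAGGTCAGTC
TGCATGGGTTCCACCGGAGTGCGGCGCATGTACGTGCACAGCACATGCTTAGATGCTAAGAAGATAGCAA
CGTGTTTATCAGCTGACATGCACTTTCTCACAGTCTTCCAGGTTGTAAGATTTAGCGAGCCTATTTCAGT
TCAACTAGCTTCAGGAGATGTTAGGCGAGTCCTGCTTCTTGGAATCTCTCATTAGCCGTTCAGCCGCGTG
GTTGTGGCGCTGTGGGAGTGTGTCTCTCGAGAAAGGCAGTCACTCAACTCGGAGCTTCGGTATTCGCGTG
ACGTCGCGAGTATCCACCTCGGATTGGAATACCTAAAGTGGCATGCAACGAGGTCGGTGTAGAAGGATTC
GGCACATGTGCCCACATCCGCCAGGTTGCATTCACGCGTTGTTCTGGCACTTTCAGATCATATGAAGTGT
ATGTATCTTCACGGTCGCCGGCTTTTGCCGCTTGTAACCTATGACGTCCGGCCTGCTATAAACGCGGGGC
TACATGTGTCGCAGGGACACTACCGTGCTACGCTATACCATAGCAGAAAACACGTTTAACACTGCAACGC
AGACATACTACTGGGTATCAAGTAACACGTCGTTCTTGCAGAGAGCTTCATCCGTCCCATACGTGCTTAA
ATGTGAGATTAGGTGTCGGGGGTCCTTTTATATGAGGCGACCAACGACCTACACGACGTCTAAACGTGCT
AGGAGTGACTGTACCTGACTATTTTTTTGTTACGATTAGACGCTTATCGTCAGCCTCAATACATCCCGAT
AAAAAAGGCCGCCATCTGTAACGCCCCCTCGAACCGCGCTGTGATAGAGACGCTACGCGCAATGAGTTAC
AGTGAAAGGAGGGGATCCATAGTAGCACGAACTCTAAAGGTGCGGCGAGGGAGTTAGTATACAACT
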