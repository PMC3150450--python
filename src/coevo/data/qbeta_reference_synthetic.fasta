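>qbeta_synthetic_reference 4217 nt synthetic stand-in for the Qbeta RNA genome (printed codon contexts embedded; remainder random non-stop codons)
ACUGCAUAUGUAAUCUACACAGCACUGGUCGUGCUAUGAUGAUGGAGCGCCAACUGGCGU
AUGCCUAUCCGUAAACCGGGAGCGGGCGACAUCGUUUGUAGAGCUGAGUUACAACUACAA
CCCGGCGGGUUCAGUACUCGGUAUGUAGCGCCGAUGAAAGGCGGUCCAAAUGCAAGUUGC
CCCAUCAGACUCUCCUGGACGCUUCGAGCACUGGGAUACCUAGCAUGGACUAAUCGUCUU
AAUAUCUCGGCCUACAUGGGGAUUAUAGAUUGCCCAGAGCUCCUACUAUCUGGGGGGGGU
ACCAGGCCAAUGAGAUAUAUGCCAACUCUUUAUGCGGUAAACCGGUGUCAUAAACAAGGA
AAUGUACGGUUGAGGAUUCAGCGACAGUCGUAUCGGCAUAGCAAGGGGGUUUAUACGACC
GUGGGUUCGCAACGGCUUGGAAACAUGUUUGUCGUACUUGCGGCGUCUCUAGCUCAUGAU
GCUAUUGCCCGUCCGGCGGACUAUAAUCCAUCCGCUGAAGGCCUCCGUCAACGUGUUCGG
GUGUCGUUGGUCUAUCUUGCGACACAAGGGCAAGACACCGAAGUCGCCGAAGCCAAGGCC
UUAUAUAAGCCCUACAACCUGCCCUCCAGAGGGUUGUCAGUCUGCGUGGCCCUGUUACUG
GACUUAUCAACCACGUAUCCUUACAUUGGGGCGGCUGUUUCUGUGUUCCCGCUCCCUCCC
GUCCUUAGCAUUAUAUUUCAGCUCAGGGUUACCAACAAGUGCAGUCUCCAGCGGCUAAUU
AGGACCGGCAGAUUAACACUGACAUCCUGCCGUGUCAAUGCCAUUGCUGUUAUUCUGAAG
UGUUGCUGGGCCAUCCGCCGUCACCGGUAUAUGACGAAUUCGAGACUCAAAUGUCACAGG
CUGCUGAUCUUUUGCAGGCCCAUCGUCAGGGUGCCUAGGAAUACAUUAACAUCGAACGGC
AGUCCAGUGGUAAUGAGGCAAUAUGGAGACAAAUGCUAUGAGUAUCAUGACCGCUGCUUC
ACUAUGCGCGUUUUCGAACGCACGGGGCACCCACCCCUCUGUUCUUUUAGAGAAGCCCUU
UCGUGCUGUCGUGCUAGUGCUGUGGACUCAAAACUUGUCUGUAAGACAACAGGAGGAAAG
CCUGGUUCCCGGUCAAGUACACAGAUCAAUCGCUGUUCUCAAAAAGCUGUGACACACAUU
UCGGGCGGGAAAAUAACCCGCAUAUGGGGUUCAUUGGUCAUAUAUGGUUCAGUGACCGGG
CUUGCGCACCAAGUCAUUACAGCCUACAGUUUGAUCAGGGAUGGUCUAUCGCUAAUAGGC
UAACGUAACAAGUCCAUGGUAGCAUGAAUAGACGAGAACGAGACUCCGUCGGUCCGUGGA
GGUCUGCGGAACCACUCGCAAGGGAUUUACUAGAUGAAGGAAAGAUUAACAACUACCCUC
CGAGUGGUCCGCAUUUAUCGGCCUCUUCUUUACCGCGCUUGGUUUAUCAUUGUUGCUGCU
UUCCUCUAAGUCCUGCGGUAAAUCUGAUAGGCUGGCCAAAUCUGAACUUCCCCACUAAUC
CCAGUUCCCUUCCAUGCAUAAGAGGACCCAAAUUCAAACUACGCUGCAUGACACCCCCCA
UUCCGGUUUUAGCAAUGGAAGGCGGCUUCGGGUAUUCUGUCGUAGGCCAUCGAAAUGCAU
GUUCAGACACUGCUGGUAUCUGUCUUGAUUCGACGUUUAUGAGUGUCAUAAAGCAUAGCU
GAUGUAGUGUACCUUCUACCGCUGAUCCUUGUUACAGAUCCAAAACGCAAUGGAUUCAUA
CUGGGCAGCUUCGUGCUCCAAGGUUGGAUACACCGCCCGGCGAAUCUACCGUAAAGAAUC
GCUGGAAGACGUCUACAGUCCAGGCUCGAACCGAGCACUAUGAUGACCCCCUCAUUCCCU
GCAAACAACAUACAUGGAGAGACAUGGCAGGAACCCCUUACUUAUCCAUUAAAAGGCAUA
UUCGCUUCCCGAGACGUAUCGCUGGGUUUGCUUCAACUGGUAACUAUACCAAUCUAGAGG
CUAGCUGGCACACAAUCCAUAAUUGGAAAACGGGCCGGAACGAUACUCUUGCGGGCGGAG
CUCUUACUGUAGUAUUUAGUCUGUUAACGCAGAUACUCACACUGAUGUCGAGCACUUACC
GCGUUCUUGGAUUGGCGGUAGAAAAAAAUCCCAAUGAGUCAUCAUACAGGCUUAAGUGGU
UACGGGACAGAGGGAGUCAGAGGCGCAGCUAUAAAUAUUGCACUUGCCCACAGGGGCUAA
GGCCGCUAGUUCCGACUUCAGGUUGGUUCUCUAUUUCCUCACCCUAUCAUUAACGCCCAA
AAACCUUGGCCAUGCAAUCCUCCGCGUCUAGUUCCAAUACAUGGCUCUACCCCCGAACGC
UUAAACCUGACACAAAACGUAGGACCCUGUUCCUCUCUAUGAUUCGCAACCCGGCGAUAA
UCCGUGGAGGUCUAACAAGACUGAAAUAUGACCCCCGACUUAAUGGACAAAGAUGGGUAA
UCAGCUGUGUGACGGUCGUAAUACUGCGACUCCUACAAAAACCUAUGAUGCCUAUGCUGU
CGUCGUCGUGGACCGCACCAGACCGGUCAUCUCUUUAUGAUGAGAUGGUGUGUUCUGCUG
AAUUCCGCGAUGCCCAGCACAAGGCGAACCGCCUUCUCCCCGCAGUUUGCCUGGCGGUGC
AUCGGCGCUCCGCCAUAAACCUGGGCGACGAAAAAGGUUGCUGCCCUUUCGGGUAUCGCC
UAGUUCGCGAAGCCCAUCAGAGCCAGGGAAUCCUUAGAAGUGUCGGGAACCAAUGCGGGU
GGGUCAGCUUGCACCCGUUAGCGUCAAAUCCAUUGGUCUACUCGCCAGCAUCCCGAGUCC
CUCGCUUUGAUCCGGGGUCAAAGGCCUCAUUAGAAAAGGAUCACCGUAAUCCCAGUCGAA
CACACGCCGUCACCGCAUGGUCCUCCUCUAUGAGCAUCUCCGGAGCGCUUUUAUGGAGAG
GAACCAAAGGAAACGUGCAAGCCCUGAUAGAGAACUCCAAGGUAUGUAUAUGCUUCUCGC
GUUCACCAGGAAAAAUGCCGAUGGAAGUGAAGCAUAGCUCUCGGCAUCGUCGUCCCACCA
CAGCCGGUUCACUCAACCGCCCAAGCCUACCGGACCUGUGGUGUUCCAGGCGCUUGGUUG
UUCCGGGGAGCUCAAGGACGUGGGUAAGAGGUGAGCACGGUAGAUAUGUUCUUCGUUAUC
UUGCAACAGCCACCUUGAUCGAGCGUGGUUUGCUUGGGUGCUUCCACUUCGUUGGAAUUA
GGUCGGUACUAUUCGAAGUCAUUAUCGCAUUAAUGCGUAGUUACCUGCAGGUCUAUAAGA
CAGCGACGCCUAAACACCAUCCAUGCUAUUCUUUAGUUACACCAUCCCCGCUUUCAGGCU
UUUCUGUGAGCAUAACCUCAGUCAAGGCAGUCGCAUAUACUCUUAUUCCUACUCGGGAUA
CCAGGUGCAGUGGCCCCGAAGCCAUCACCUUAGAAAAUUUUUAUUCUGUUAACGGAGGCU
AUUUGCGCUACGCUUGUGAUUCUCCCGGCCCCUGGCGACUUACGAUGUCUCUAUGCGCGC
AGCCGGCUCGGGUUACUCGUAUCGUAUCGAACCCAGCUGAUCCCCAAACCUACGAGCAAU
GUGACGUAAAUGCCCAAGGUAAUAGAUAUCGUAUUGAACGCGAGACGUUUACGUCAAAGC
CGUCCAGGAUAUUAUUAGACACUUCCUUAAACAGCAAUAACUGCGACCAUCAUUCAGGGA
CGUUCACGCGGUACCCGGGAGUUGAACCAAUAAAUUUGUCCCUAGGGAGUAGUCGAAAAC
CUGUGAUGCAGGUCUCAGGACCGGUCUCUAUGACUCACCGUUCCAGACUCUAUCCUAAGG
CUGUUAUGCCAGAACCUCUUCGAAUGCAUGAGACACGAGAAACAUCGACUGCCGCCUCAU
CUGACUCAGAGACCUGUCCGGGGUACUGUGAAGUUUGCACCGUAAUACACUGCGUGUUUA
CACCACGCAAGGCAGCCUCACACAUUAGCAUUAUUCAGGCUUUAGGCCGAACAUCAUCGU
CCAGUUGGGACAAAUCCUGCCCUGGAAUAAUCAGAUAAACUAAGUAACCAUUUAAGUUGU
AUUGCUAAGCAUGAGAGGCACGACGAAGUGAUUAUAUUUUGUGUACCGCUACCUCUUUUU
UUUGUGGUCCCGCACGG
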