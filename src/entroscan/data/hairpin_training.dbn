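>hp01
UUGUGCCUAUGCCCCCGCAUAGGCAUAA
...((((((((......))))))))...
>hp02
UAAAGCUGGCCAAGCCGCCAGCUUA
..((((((((......)))))))).
>hp03
GGGGUGGAGGUCGACCAUCACCUCCACGACA
...((((((((........))))))))....
>hp04
UUGAAUCGCUGAGAUAUGA
....(((.....)))....
>hp05
AUGCGGCCCAUCGCGACGGGCCG
....(((((........))))).
>hp06
UAGUCGGCGGUAUAGUACGCCGGU
....(((((........)))))..
>hp07
CACACUGCCGUGUUGGU
.((((....))))....
>hp08
CCAAGCUCUACGUCUGGGGUAGAGCAUUA
....(((((((.......)))))))....
>hp09
AUUUCGGCUCGGAACGUCGAGCCGGUA
....(((((((......)))))))...
>hp10
GACCAGAGUGGUA
.((((...)))).
>hp11
UAUGUGGAGAUCCACACCAG
..(((((....)))))....
>hp12
GGUUCUGAGUAGGGCAGC
....(((.......))).
>hp13
GACAUUAAGCGUCCUAAGU
....(((.......)))..
>hp14
ACGCCCCAGGCAGGGGCGAAAU
.((((((.....))))))....
>hp15
GCACUGACUCGAGGGAGUCAGGUAA
...(((((((....)))))))....
>hp16
UGUAAGGGUUUGCGCCCUUACU
.(((((((......))))))).
>hp17
CACCCAUGCGGCUUGGGUUAU
..((((.......))))....
>hp18
CUAAUAAGCGAUCGACGCUUAUUAC
.((((((((.......)))))))).
>hp19
UCAUUUCCCAAGAAAAUGC
.(((((.......))))).
>hp20
UUGCGCGGGCGUAAGCCCGCGCA
..((((((((....)))))))).
>hp21
GUCGCUACGACCUGUGGCGUAGCGCAUA
..(((((((........)))))))....
>hp22
CCGUGCUAGAUGUCUGGCUAGCCGAG
....(((((........)))))....
>hp23
CGGAGAUCCGGGAGGUGGAUCUA
...((((((.......)))))).
>hp24
CGCCAUACGGGUCGUGCCGUAUGUCC
...(((((((......)))))))...
>hp25
GGGGGCUCUGCGACAGCGCAA
....(((.......)))....
>hp26
CGCUCCCGUUCCCGGGAGAUCC
..((((((....))))))....
>hp27
ACUCUUCGCCAAGUAU
...(((....)))...
>hp28
CACAGCGCGCCGGCUGCGCUGAC
..((((((.......))))))..
>hp29
CGAACGCUGGGGCCCCCAGCGUUCG
.((((((((.......)))))))).
>hp30
CAAUAACUAAACUAGUUA
....(((((...))))).
>hp31
UUACCCUAUUGAGGGAUAGGA
....(((((......))))).
>hp32
CAAAUUGGGGUGCGAGGCUCACCCCAACCUA
....((((((((.......))))))))....
>hp33
AUAGUCAGCAGGCCUCCUGACGAG
...(((((........)))))...
>hp34
CACGGCGCUCGGCGUUGC
.(((........)))...
>hp35
CUGCGCCGCAACAA
.(((...)))....
>hp36
UCAACCGUCGGAACGGUUU
..((((((....)))))).
>hp37
UCGUUAGCGACUAACCU
..(((((...)))))..
>hp38
GACAAGUGGCGGGCCACUUGUAGCA
.((((((((....))))))))....
>hp39
AAAUAGGCCCGGGAUGGCCUAUUAC
...((((((......))))))....
>hp40
AUCUCUAACGGCACUCCGUUAGAUAC
....(((((((....)))))))....
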