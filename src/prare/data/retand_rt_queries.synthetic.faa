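>Retand|Tat4-1
NMETDVLMHTMMHEWRESRAAMCFDIMLEGMRWWMHIDCHHFYLRADQQRFRDQWKQEAR
EENCAVMRLTCVAYMKYAKTVPILGQDYKGNPHFVGYPDHGNQGYRDWESMLDDDNCRVF
CNRCDDWFLILTLGKCSQAAILWILLGWCLNYINLDRNT
>Retand|Gret1
NMETDVLMHTMMHRWREHRAAMCGDIMLEGMRWWMHIDPCHFDLRADQQRFRWQMKQEAR
AEVCEVMQLTCVAYMKYAKLVPCYTQDYKGNPHFVGYPDHGNQGERDPESMLDDDNCWVF
CIRCDDWFEICILGKCSQATQLWILLHWCLNYINLDRNT
>Retand|Cinful-1
NMETDVLMHTMMHEWRESRAAYCGDIMLEGMRWWMHLDEEHFDLRADQQRFRWQWKQEAR
EENMEVMQMTCVAYMKYAKLVPIYTQDYKGNPTFVRYPDHGNQGYRDPESMLDDLNCRVF
CIRCDDWFLTLTLGQCSQATILWILLHWCLYYINLDRNT
>Retand|Grande1-4
VNMETDVLMHTMMHEWRESIAAMCGDIKLEGMRWWMHIDYHHFDQRADQQDFRWTWPQES
REENCEVMQLTCVAYMKYAKLVPIYTQDYKGNPHYVGYPDHGNQGERDPEEMLDDDNCRV
FCTRNDDWFHILTLGKCSQATILWILLHWCLNYINLDRNT
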