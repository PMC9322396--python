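>tir_seed_1
DHFLNGCKHSTQAPQDAWHRSYELSGNDHSHCEMSSNGNNHTTDQERGMVADRLPTKPES
RMDFRHRDMVIWWCQIFTTTMESDSTYPGHVVCDKIQYMCIHSDYGGQIMIQRIFWSMIK
>tir_seed_2
RHFLMAGKHSTQAPQDAWHGSYELSYNDHSRCEHCFNGNNHTTDSERGMVAQDLPAKPES
RMSNRHRDMVIWWTQIFTTTMKSDSTYPCMLVCERIQPMCIHSAFEGQIKIIRIFWSMYK
>tir_seed_3
RHYLNGGKHSTAAPQDAWDGSYELSYNDHGHCPHSSNGNNHTKDQCRGMVADGLPYKPRS
RMSFRHRTMVIVWNQIFTTTMESDSTYPGSGWFQRIQPMCITSAFGGQIWFHRIFCSMYK
>tir_seed_4
DHFLNGFKHSTQAPPGAWHGSYELSWNDWSHCRQSSNGNNHTTDQNAGVVADRLPYKPES
RMSFRHRDMVIWWCQIFPWHMESDSNYPGQGVCQRIQPWCITSAFGGQIKIHRIFWSMPK
>tir_seed_5
RHFLNGGKHSTQAPQDNWHGSECSSYNDHIHCEHSSNGNNITTDLENGGVADRHQYKPES
RGSFRHRDMVIWGCQIFTTTMEEDSTYPGMGVCQRIQPMCITSAFGAQIKILRIFSSTYK
>tir_seed_6
RHHLNGGKHLTQAPCDAWHGCYELSYNDHSHAEHSSVGMNHTTDGPRGMVADRKPYKPES
VMSFRFRDMVIWWCQIFITTGSSDSTYPGMGVCMRIQYMCITSAFGGQIKIHTIFWSMYK
>tir_seed_7
RHFLNGFKHSTQAIQDAWHASPELSYNDHSHCWHSSNGNNHTTDAEIGMVASRLPYKPES
RMSFRHRDMVDWWCQIFPTTMESQSTCPGMIACQRIQPDCITSAAGGQPKIHRIFWPMYK
>tir_seed_8
RHNGNGGKHSTQAPQDAWHGSYELSYNDHLHCEHSSNGNNHTTKQERGMVADRLPYKPTR
RMSWRHRWMVIWFCPIFFTGMEWDSTYNYMGVCQRCQPMCITSAFGGQVKIHRIFWSMYG
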