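>rpw8_seed_1
KIETYRPIHMEHEIANGTSWLRPFGMFENYQLTTACQPMAGDFKEIWYRDNKKFPMNHVT
NSKWFDPYWTWKPWVIVFFQCNACWERDQE
>rpw8_seed_2
KIEWYRPVHMEHEIQNGTSWLRPYGMYEWYYLTTACAPMAGDFKEIWSRNCKKFPKNHVT
AFKWQDPYHEWKPWYGAFFQCNLCWERDHN
>rpw8_seed_3
KMEEYRPIHMEHEIQFGLSWLGPWGMWEWYAETTWCQPMAGDFKEIWYRNCKKFPMNHVT
AGKWCDPYWEWKTWRCEFSQCNLCWRRDHE
>rpw8_seed_4
KTEEKRPIHMEHEIQNGTSYDGPGGMLEWYQLTTACQPMTGDFKEIWFRNCKKFPMNHVI
ARKWIDPYWEWKPWVGANFQGNLCFERDHE
>rpw8_seed_5
KIEEYMPILMEHYIQNGTSWLGQFGMFEWYQLTTTCQPMAGWFKEIWYRNCQKFPMNHVT
AHKWCIPYWEMKPWVGAFGQHNLRMERDHE
>rpw8_seed_6
AIEEIRPIHMEHELMNGTSWLGPFGHFEKGQLTTMCRYMAGDFKEIWYRNCKKEPVNHVT
AGKWCDPYWEWKPWVGAFFACNLCYERDHE
>rpw8_seed_7
KIEEYRPEHMEHNIQNGTLWLGPFGMFEWYQLTTRCQPMAGDFKEIWYYNEKKDPMNHVR
AGKWCDPYWETKPWCDAFDQCNHCWERVHE
>rpw8_seed_8
EIAEYRPIHMNHEDQNGTSWLGHFGMFIWYQLTTACQPMAGDFKEIWYRNCWKFPMNHVT
KGKECFPYWEWKWIDGAFFQVNLCWERDHE
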