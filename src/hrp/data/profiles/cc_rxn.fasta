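>cc_rxn_seed_1
FCRELLWVQCDICRRSIRCIGMTQGTDAGEQRVVHHKELGHHFWN
>cc_rxn_seed_2
HCELLLWVMTWCCRTLIRCPGMTQGTDAGEQRVVEHKELGHIFWH
>cc_rxn_seed_3
FCELLLWVPDDICRTEIRCIGMKQGTDARYQCVVEEKELGHHFWH
>cc_rxn_seed_4
FQELLLWVMDDACSTSIRCIGMTLGTDPGEQRVVEHKEPGHHFWD
>cc_rxn_seed_5
FCMGLLWVMDDIMRTSIRCIGQTIGTDAGEQHVVEHKELGHHKWH
>cc_rxn_seed_6
FCELLLHVMDSICRTSIRCIGMTNGTDADEPRVVEHKELGHKFGH
>cc_rxn_seed_7
FCELLGWVMDDICKNSIRCIGMTQGTMAGEQRVVEHAEQGHHFWW
>cc_rxn_seed_8
FCELLNWVMDDICRTRIRCIRMTQGTDAGEQRVVEHKESGPIFWC
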