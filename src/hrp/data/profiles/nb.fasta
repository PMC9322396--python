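>nb_seed_1
FMSQVGWDEQQCTECKYNTHALPCATTEGNPFYPDMMFEATVNVSSLAAKFIMPVMQEAT
FELKLMQNKLKFRPQIECMRGAQKDLTKKRVDAQLRDKQNETIFQSLQFGGAATWVFSSR
QGDMRLNQWGWIHIWFRINDWNECDKYEPKQMLSGKMGILDWKPRWVYSDSSQHPVWYSN
YGPDCRGWMWKQAMHCLHDM
>nb_seed_2
PVGDVCSDKAQCTECRYNTPALPVVFTEGNPFYPDMMFMTTVNPSSLTAKFIAGVMQEAT
FELKGKWNKLKFRPQIECMRGAQKDLTKKRVDAQLVDKQSEMIYQSLSFGGLATSVDSSR
NWDIRLNQWGWIHIWWGINDINQKTKGECKDMLSGKMGILDWKPQPVYFDSSQNPVWYSN
LQCDCRGWMWKQMVDCHHDM
>nb_seed_3
FVRDVMSDEAPCTEDKYWTHANPVVTEEGNPFYPDMMFEATVNVSSLAAKFIVYVMQEYT
FELKGKFNKLKFRPQIGCTRTAQKDLTKKEVDAQLRDKQNEMIFQSLIFGGVATSVDSIR
QHDIRLNQGDWDHYWWGINDWNEKDKGECAQMLSGEMGELQRKPRPVPSDSSYNPYWYSE
YQRDCRCWMWKQAVHCHHDM
>nb_seed_4
FVKDWMSDEFQCTECKYNYHALPVVTTNGNPTYMDMMFEANVNVCSLAAKFIECVMQQAT
FELKGKFNKCKHRPQIRCMRGAQKDLTKKRVDAQNRSKQREDIFQILIFGGQAWSVDSSR
QHDIHLNQWGWIHITWGINDCNEKDKGECKSMLSGKMGITDNKPRPVYSDSSQNWVWYSN
KQPDCRGWMWKMAEHCHHDH
>nb_seed_5
FGKDVMSDEAQCQECKYNTHFLPRVTTEGNPFYPDEMFEATVNVSSLAAKMIECVMQEAT
FKLKGTNNKLAFRPQIGCSRGVRKDLTKKLVPAQLRHKHNEMIFESVIQGGLATSVDSSR
QHDCRLNQWGTIKIWWGINDWKVKDKGECKQMASGKCGILDWKPVPIYSDSSQNPVWYSN
YQPDCRGWMWKQAVHCHHDM
>nb_seed_6
FVSHNMNDEAQCTGCKYNTAALPVPTTSCNPFYEDMNFEATVNVSSLAAKFIECVTQEAT
FELKGKFNKLKFRPWIECMRGAQKDLTYKRVDAQLRDKQNEMIFQSKIFGGLWTSVDLNR
QHYITLNQWGWIHIWWGINDWNEKDKGCEGQMLSGKMGILDAKPQPMYSDSSQQPLVYPN
YQPDCRGWMWKQAVHCHHDM
>nb_seed_7
FTKDVMSDEAQCTECKYNTHALPVVTTEGNPFYLDMEKEATVNVSHNAALFIECVMQEAT
FNLKGKFAKLKFRDVIELMRGAQKDLTKKVDDAQLRDKQNEMIDQTYIFGGLATSVDSSR
QHGIRLNQWGWIHIYMGINDWNEKDKGEAKQMSSGKMGILDWKWRFVYNDSSQNPVYYNH
YQPDGRGWMWKQAVHCHLDM
>nb_seed_8
FVKSVMSDEAQCTECKLFWFALPVVTTEGNPFYPDNMFEATVNVSFLAAKFIEDVIQEAT
FDLFGKFNKLKFRPQIECMRGAYKDLTKKRVDADLRDKQNEMIFQSLIFIGLATIVISSR
QHDICLVQWYWPHIWWGINDWNEKDKGECKQMLSFKMGIVDWGPRSVNSDVSQIPVWYSV
YQSDCRGWMWKQAVHCHHIM
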