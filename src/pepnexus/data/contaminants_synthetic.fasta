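>albumin_like_synthetic stand-in for serum albumin; synthetic sequence, not the real protein
MKWVTFLLLLFVSGSAFSRGVFRRDTHKSEIAHRFKDLGEEHFKGLVLVAFSQYLQQCPF
DEHVKLVNELTEFAKTCVADESHAGCEKSLHTLFGDELCKVASLRETYGDMADCCEKQEP
ERNECFLSHKDDSPDLPKLKPDPNTLCDEFKADEKKFWGKYLYEIARRHPYFYAPELLYY
>collagen_like_synthetic stand-in for fibrillar collagen; synthetic Gly-X-Y repeat
GPPGPAGPPGEAGKPGEQGVPGDLGAPGPSGARGERGFPGERGVQGPPGPAGPRGANGAP
GNDGAKGDAGAPGAPGSQGAPGLQGMPGERGAAGLPGPKGDRGDAGPKGADGSPGKDGVR
>keratin_like_synthetic stand-in for human keratin; synthetic coiled-coil-like sequence
MSRQFSSRSGLGGGFSSGGFSGGSFSRGSSGGGCFGGSSGGYGGLGGFGGGSFHGSYGSS
SFGGSYGGSFGGGNFGGGSFGGGSFGGGGFGGGGFGGGFGGGFGGDGGLLSGNEKVTMQN
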