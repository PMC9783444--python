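lobe,hemisphere,label,name
frontal,left,1003,caudal middle frontal
frontal,left,1012,lateral orbitofrontal
frontal,left,1014,medial orbitofrontal
frontal,left,1017,paracentral
frontal,left,1018,pars opercularis
frontal,left,1019,pars orbitalis
frontal,left,1020,pars triangularis
frontal,left,1024,precentral
frontal,left,1027,rostral middle frontal
frontal,left,1028,superior frontal
frontal,left,1032,frontal pole
temporal,left,1001,bankssts
temporal,left,1006,entorhinal
temporal,left,1007,fusiform
temporal,left,1009,inferior temporal
temporal,left,1015,middle temporal
temporal,left,1016,parahippocampal
temporal,left,1030,superior temporal
temporal,left,1033,temporal pole
temporal,left,1034,transverse temporal
parietal,left,1008,inferior parietal
parietal,left,1022,postcentral
parietal,left,1025,precuneus
parietal,left,1029,superior parietal
parietal,left,1031,supramarginal
occipital,left,1005,cuneus
occipital,left,1011,lateral occipital
occipital,left,1013,lingual
occipital,left,1021,pericalcarine
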