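specimen_id,taxon,group,sex,lumbar_count,level,ventral_height,dorsal_height,sup_dv_diameter,inf_dv_diameter,max_inter_IAF,max_inter_SAF
MH2,Australopithecus sediba,A. sediba,F,5,L2,21.0,22.5,20.8,21.1,23.0,
MH2,Australopithecus sediba,A. sediba,F,5,L3,21.75,22.25,21.4,21.0,25.0,24.0
MH2,Australopithecus sediba,A. sediba,F,5,L4,22.1,21.5,22.2,21.2,(28.0),
MH2,Australopithecus sediba,A. sediba,F,5,L5,21.0,17.0,21.4,19.8,(33.0),28.5
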