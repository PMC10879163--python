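parcel_id,name,group
DG,Dentate gyrus,DG
CA1,Cornu Ammonis 1,CA3+CA1
CA2,Cornu Ammonis 2,CA3+CA1
CA3,Cornu Ammonis 3,CA3+CA1
SUB,Subiculum,Sub
ENTl,Lateral entorhinal cortex,LEC
ENTm-d,Medial entorhinal cortex dorsal zone,dMEC
PAR,Parasubiculum,ParaS
POST,Postsubiculum,PostS
PRE,Presubiculum,PreS
HPF-other,Retrohippocampal region,Retrohipp
RSPd,Retrosplenial dorsal (granular),DV(gr.)RtSpl
RSPv,Retrosplenial ventral (granular),DV(gr.)RtSpl
RSPagl,Retrosplenial lateral (agranular),L(ag.)RtSpl
MB,Midbrain,MidB
SCm,Superior colliculus motor,MidB
IC,Inferior colliculus,MidB
HY,Hypothalamus,Hyp
PMd,Dorsal premammillary nucleus,PMdv+TU
PMv,Ventral premammillary nucleus,PMdv+TU
TU,Tuberal nucleus,PMdv+TU
MM,Medial mammillary nucleus,MM+LZ
LZ,Hypothalamic lateral zone,MM+LZ
MBO,Mammillary body,MBO+LM
LM,Lateral mammillary nucleus,MBO+LM
AMm,Anteromedial nucleus medial,mATN+PT
PT,Parataenial nucleus,mATN+PT
TH-other,Thalamus other,TH+LGN
LGd,Lateral geniculate dorsal,TH+LGN
AD,Anterodorsal nucleus,LD+AD
LD,Lateral dorsal nucleus,LD+AD
AV,Anteroventral nucleus,dvATN+MGN
AMd,Anteromedial nucleus dorsal,dvATN+MGN
MG,Medial geniculate nucleus,dvATN+MGN
IAD,Interanterodorsal nucleus,IAD+IAM
IAM,Interanteromedial nucleus,IAD+IAM
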