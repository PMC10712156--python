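sample_id,seed_index,called_species,average_score,original_identification
MIRL22-A.unknown-07,1,Amaranthus retroflexus,2.62,Amaranthus retroflexus
MIRL22-A.unknown-07,2,Amaranthus retroflexus,2.59,Amaranthus retroflexus
MIRL22-A.unknown-07,3,Amaranthus retroflexus,2.64,Amaranthus retroflexus
MIRL22-A.unknown-08,1,Amaranthus retroflexus,2.69,Amaranthus retroflexus
MIRL22-A.unknown-08,2,Amaranthus retroflexus,2.66,Amaranthus retroflexus
MIRL22-A.unknown-08,3,Amaranthus retroflexus,2.65,Amaranthus retroflexus
MIRL22-A.unknown-09,1,Amaranthus tuberculatus,2.21,Amaranthus tuberculatus
MIRL22-A.unknown-09,2,Amaranthus tuberculatus,2.26,Amaranthus tuberculatus
MIRL22-A.unknown-09,3,Amaranthus arenicola,1.79,Amaranthus tuberculatus
MIRL22-A.unknown-10,1,Amaranthus arenicola,2.05,Amaranthus arenicola
MIRL22-A.unknown-10,2,Amaranthus arenicola,1.95,Amaranthus arenicola
MIRL22-A.unknown-10,3,Amaranthus arenicola,2.04,Amaranthus arenicola
MIRL22-A.unknown-11,1,Amaranthus tuberculatus,2.28,Amaranthus tuberculatus/rudis
MIRL22-A.unknown-11,2,Amaranthus tuberculatus,2.03,Amaranthus tuberculatus/rudis
MIRL22-A.unknown-11,3,Amaranthus rudis,2.14,Amaranthus tuberculatus/rudis
MIRL22-A.unknown-12,1,Amaranthus retroflexus,2.69,Amaranthus retroflexus
MIRL22-A.unknown-12,2,Amaranthus retroflexus,2.65,Amaranthus retroflexus
MIRL22-A.unknown-12,3,Amaranthus retroflexus,2.57,Amaranthus retroflexus
MIRL22-A.unknown-14,1,Amaranthus hybridus,2.45,Amaranthus hybridus
MIRL22-A.unknown-14,2,Amaranthus hybridus,2.31,Amaranthus hybridus
MIRL22-A.unknown-14,3,Amaranthus hybridus,2.34,Amaranthus hybridus
MIRL22-A.unknown-16,1,Amaranthus palmeri,2.28,Amaranthus palmeri
MIRL22-A.unknown-16,2,Amaranthus palmeri,2.12,Amaranthus palmeri
MIRL22-A.unknown-16,3,Amaranthus palmeri,2.25,Amaranthus palmeri
MIRL22-A.unknown-17,1,Amaranthus hypochondriacus,1.81,Amaranthus hypochondriacus
MIRL22-A.unknown-17,2,Amaranthus hypochondriacus,1.80,Amaranthus hypochondriacus
MIRL22-A.unknown-17,3,Amaranthus hypochondriacus,1.88,Amaranthus hypochondriacus
MIRL22-A.unknown-18,1,Amaranthus spinosus,2.44,Amaranthus spinosus
MIRL22-A.unknown-18,2,Amaranthus spinosus,2.40,Amaranthus spinosus
MIRL22-A.unknown-18,3,Amaranthus spinosus,2.39,Amaranthus spinosus
MIRL22-A.unknown-19,1,Amaranthus tuberculatus,2.33,Amaranthus tuberculatus/rudis
MIRL22-A.unknown-19,2,Amaranthus tuberculatus,2.18,Amaranthus tuberculatus/rudis
MIRL22-A.unknown-19,3,Amaranthus tuberculatus,1.95,Amaranthus tuberculatus/rudis
MIRL22-A.unknown-20,1,Amaranthus retroflexus,2.43,Amaranthus retroflexus
MIRL22-A.unknown-20,2,Amaranthus retroflexus,2.43,Amaranthus retroflexus
MIRL22-A.unknown-20,3,Amaranthus retroflexus,2.38,Amaranthus retroflexus
MIRL22-A.unknown-21,1,Amaranthus powelli,2.49,Amaranthus powelli
MIRL22-A.unknown-21,2,Amaranthus powelli,2.51,Amaranthus powelli
MIRL22-A.unknown-21,3,Amaranthus powelli,2.47,Amaranthus powelli
MIRL22-A.unknown-22,1,Amaranthus albus,2.27,Amaranthus albus
MIRL22-A.unknown-22,2,Amaranthus albus,2.30,Amaranthus albus
MIRL22-A.unknown-22,3,Amaranthus albus,2.31,Amaranthus albus
MIRL22-A.unknown-23,1,Amaranthus blitoides,2.57,Amaranthus blitoides
MIRL22-A.unknown-23,2,Amaranthus blitoides,2.53,Amaranthus blitoides
MIRL22-A.unknown-23,3,Amaranthus blitoides,2.63,Amaranthus blitoides
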