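sample_id,called_species,average_score,reference_species,atypical,excluded
MIRL22-A.unknown-24,Amaranthus spinosus,1.30,Amaranthus palmeri,1,0
MIRL22-A.unknown-25,Amaranthus retroflexus,2.47,Amaranthus retroflexus,0,0
MIRL22-A.unknown-26,Amaranthus tricolor,1.92,Amaranthus tricolor,0,0
MIRL22-A.unknown-27,Amaranthus powelli,2.14,Amaranthus powellii subsp. powellii,0,0
MIRL22-A.unknown-28,Amaranthus caudatus,2.31,Amaranthus caudatus,0,0
MIRL22-A.unknown-29,Amaranthus palmeri,2.11,Amaranthus palmeri,0,0
MIRL22-A.unknown-30,Amaranthus arenicola,1.95,Amaranthus arenicola,0,0
MIRL22-A.unknown-31,Amaranthus albus,2.04,Amaranthus albus,0,0
MIRL22-A.unknown-32,Amaranthus tuberculatus,2.16,Amaranthus tuberculatus,1,0
MIRL22-A.unknown-33,Amaranthus californicus,2.25,Amaranthus californicus,0,0
MIRL22-A.unknown-34,Amaranthus californicus,2.26,Amaranthus californicus,0,0
MIRL22-A.unknown-35,Amaranthus spinosus,2.24,Amaranthus spinosus,0,0
MIRL22-A.unknown-36,Amaranthus caudatus,2.34,Amaranthus caudatus,0,0
MIRL22-A.unknown-37,,,,0,1
MIRL22-A.unknown-38,Amaranthus tuberculatus,2.09,Amaranthus tuberculatus,0,0
MIRL22-A.unknown-39,Amaranthus albus,1.92,Amaranthus albus,0,0
MIRL22-A.unknown-40,Amaranthus californicus,2.30,Amaranthus californicus,0,0
MIRL22-A.unknown-41,Amaranthus powelli,2.16,Amaranthus powellii,0,0
MIRL22-A.unknown-42,Amaranthus albus,2.19,Amaranthus albus,1,0
MIRL22-A.unknown-43,Amaranthus hypochondriacus,1.80,Amaranthus cruentus,0,0
MIRL22-A.unknown-44,Amaranthus hybridus,2.42,Amaranthus hybridus,0,0
MIRL22-A.unknown-45,Amaranthus albus,2.08,Amaranthus albus,0,0
MIRL22-A.unknown-46,Amaranthus retroflexus,2.05,Amaranthus retroflexus,1,0
MIRL22-A.unknown-47,Amaranthus powelli,2.41,Amaranthus powellii subsp. bouchonii,0,0
MIRL22-A.unknown-48,Amaranthus powelli,2.23,Amaranthus powellii subsp. powellii,0,0
MIRL22-A.unknown-49,,,,0,1
MIRL22-A.unknown-50,Amaranthus hypochondriacus,2.03,Amaranthus cruentus,0,0
MIRL22-A.unknown-51,Amaranthus tuberculatus,2.17,Amaranthus tuberculatus,1,0
MIRL22-A.unknown-52,Amaranthus tuberculatus,2.27,Amaranthus tuberculatus,0,0
MIRL22-A.unknown-53,Amaranthus spinosus,2.20,Amaranthus spinosus,0,0
MIRL22-A.unknown-54,Amaranthus albus,1.72,Amaranthus albus,0,0
MIRL22-A.unknown-55,Amaranthus palmeri,1.49,Amaranthus palmeri,1,0
MIRL22-A.unknown-56,Amaranthus tricolor,2.22,Amaranthus tricolor,0,0
MIRL22-A.unknown-57,Amaranthus watsonii,2.00,Amaranthus palmeri,0,0
MIRL22-A.unknown-58,Amaranthus powelli,1.92,Amaranthus powellii subsp. powellii,0,0
MIRL22-A.unknown-59,Amaranthus hybridus,2.21,Amaranthus hybridus,0,0
MIRL22-A.unknown-60,Amaranthus hypochondriacus,1.97,Amaranthus caudatus,0,0
MIRL22-A.unknown-61,Amaranthus arenicola,2.14,Amaranthus arenicola,0,0
MIRL22-A.unknown-62,Amaranthus tricolor,2.14,Amaranthus tricolor,0,0
MIRL22-A.unknown-63,Amaranthus powelli,2.32,Amaranthus powellii subsp. bouchonii,0,0
MIRL22-A.unknown-64,Amaranthus retroflexus,2.35,Amaranthus retroflexus,0,0
MIRL22-A.unknown-65,Amaranthus retroflexus,1.97,Amaranthus retroflexus,1,0
MIRL22-A.unknown-66,Amaranthus retroflexus,2.02,Amaranthus retroflexus,0,0
MIRL22-A.unknown-67,Amaranthus retroflexus,2.40,Amaranthus retroflexus,0,0
MIRL22-A.unknown-68,FLATLINE,0.00,Amaranthus palmeri,1,0
MIRL22-A.unknown-69,Amaranthus arenicola,2.03,Amaranthus arenicola,0,0
MIRL22-A.unknown-70,FLATLINE,0.00,Amaranthus tuberculatus,1,0
MIRL22-A.unknown-71,,,,0,1
MIRL22-A.unknown-72,Amaranthus palmeri,2.05,Amaranthus palmeri,0,0
MIRL22-A.unknown-73,Amaranthus watsonii,2.02,Amaranthus palmeri,0,0
MIRL22-A.unknown-74,Amaranthus hybridus,2.43,Amaranthus hybridus,0,0
MIRL22-A.unknown-75,Amaranthus powelli,1.90,Amaranthus powellii subsp. bouchonii,0,0
MIRL22-A.unknown-76,Amaranthus californicus,2.14,Amaranthus californicus,0,0
MIRL22-A.unknown-77,Amaranthus retroflexus,2.30,Amaranthus retroflexus,0,0
MIRL22-A.unknown-78,Amaranthus retroflexus,2.16,Amaranthus retroflexus,0,0
MIRL22-A.unknown-79,Amaranthus powelli,2.52,Amaranthus powellii,0,0
MIRL22-A.unknown-80,Amaranthus tricolor,2.09,Amaranthus tricolor,0,0
MIRL22-A.unknown-81,Amaranthus caudatus,2.43,Amaranthus caudatus,0,0
MIRL22-A.unknown-82,Amaranthus spinosus,2.04,Amaranthus spinosus,0,0
MIRL22-A.unknown-83,Amaranthus retroflexus,2.12,Amaranthus retroflexus,0,0
MIRL22-A.unknown-84,Amaranthus powelli,2.40,Amaranthus powellii subsp. bouchonii,0,0
MIRL22-A.unknown-85,Amaranthus albus,1.97,Amaranthus albus,1,0
MIRL22-A.unknown-86,Amaranthus retroflexus,2.41,Amaranthus retroflexus,0,0
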