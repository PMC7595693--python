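image_id,condition,percent_overlapping,percent_in_granules_overlapping
localizing_1,localizing,61.4276,51.1677
localizing_2,localizing,60.3601,35.9508
dispersed_1,dispersed,0.0000,0.0000
dispersed_2,dispersed,15.1641,9.9410
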