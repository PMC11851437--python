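site,habitat_type,natural_reach_km
S1,TR,81.0
S2,TR,17.0
S3,NRAD,106
S4,TR,27.0
S5,TR,6.0
S6,TR,23.0
S7,TR,7.0
S8,NRAD,110
S9,NRAD,110
S10,NRAD,56.0
S11,NRAD,56.0
S12,NRAD,350
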