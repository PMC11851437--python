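metric,S1,S2,S3-S4,S5-S6,S7,S8,S9,S10-S12
NFM,26.9,19.3,17.2,19.7,20.7,24.4,27.2,28.4
PF,9.6,10.2,8.9,8.5,8.6,9.2,8.0,9.6
HYF,38.5,38.6,36.2,40.2,44.0,40.5,38.4,38.5
CUF,17.3,31.8,37.1,35.0,30.2,32.1,23.2,18.4
LAF,51.9,48.8,48.6,50,51.7,55.0,56.8,56.1
SIF,7.7,4.5,5.7,4.9,5.2,4.6,4.8,5.3
FLF,3.8,4.5,3.8,4.9,5.2,4.6,5.6,6.1
SPF,3.8,2.3,1.9,2.5,2.6,2.3,2.4,1.9
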