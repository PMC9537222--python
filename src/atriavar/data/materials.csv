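material,cv_long,cv_trans,conductive,mixture
RA,78.51,30.52,1,RA:80.0;AVR:7.9;RAA:12.1
CT,86.52,33.66,1,RA:24.6;CT/BBra:73.3;PM:2.1
PV,58.64,43.98,1,RA:0.1;LA:99.9
BB/PM,100.12,39.21,1,RA:44.0;CT/BBra:9.8;LA:5.1;BBla:21.6;PM:19.5
ISTMO,66.27,66.27,1,RA:100.0
SAN,23.29,23.29,1,RA:97.6;PM:2.5
FO,0,0,0,
CS,92.82,58.11,1,RA:100.0
LA,62.99,30.72,1,RA:0.4;CT/BBra:12.0;LA:69.7;LAA:18.0
FO_RING,85.00,33.11,1,RA:100.0
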