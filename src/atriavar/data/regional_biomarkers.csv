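region,RMP_mean,RMP_sd,APA_mean,APA_sd,APD20_mean,APD20_sd,APD50_mean,APD50_sd,APD90_mean,APD90_sd
RA,-78,12,116.6,14,30,18,72.2,37,200,62
RAA,-79,6.6,124.1,19,30,18,105.6,36,190,22
LA,-78,5.4,112.4,13,30,18,54.7,17,174,34
LAA,-73.8,6.6,128,19,30,18,89.7,13,160,22
AVR,-73.8,1.4,127.3,21,30,18,38,21,170,29
CT/BBra,-77,1.9,134.8,19,30,18,119.3,32,219,64
BBla,-77,1.9,124.1,19,30,18,94.2,32,172,32
PM,-75.9,12,131.6,16,30,18,74.5,17,172,19
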