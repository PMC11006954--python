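rmu_center,name,identified
160.0,A2,1
168.0,A2B,1
176.0,FA2,1
184.0,FA2B,1
196.0,A2[6]G1,1
203.0,A2[3]G1,1
210.0,FA2[6]G1,1
228.0,FA2[3]G1,1
235.0,FA2BG1,1
242.0,A2G2,1
249.0,A2BG2,1
256.0,FA2G2,1
263.0,FA2BG2,1
270.0,A2G1S1,1
278.0,A2G2S1,1
286.0,FA2G2S1,1
294.0,FA2BG2S1,1
302.0,A2G2S2,1
310.0,FA2G2S2,1
318.0,FA2BG2S2,1
334.0,UNIDENTIFIED,0
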