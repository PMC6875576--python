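metric,code,direction,min,q25,q50,q75,max
Hemiptera abundance,Hem Abun,decrease,7,9,12,16.5,20
%Coleoptera + Hemiptera,%Col + Hem,decrease,9.68,10.60,15.05,19.91,33.33
%Chironomidae + Oligochaeta,%Chi + Oli,increase,42.03,56.63,65.24,67.60,73.12
Evenness index,Even Ind,decrease,0.41,0.56,0.61,0.66,0.77
Log very large body size,Log VeL,decrease,0.060,0.065,0.092,0.145,0.21
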