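region,group,dbp_amph_mean,dbp_amph_sd,ddbp_mean,ddbp_sd
Pu,all,21.6,5.1,26.4,13.9
VSt,all,26.5,7.7,18.2,17.1
Ca,all,15.6,5.7,10.3,45.9
SN,all,27.8,10.9,33.2,51.8
GP,all,15.9,7.7,31.7,44.6
Pu,20 mg,23.6,4.6,16.4,11.3
VSt,20 mg,25.4,8.0,13.8,14.1
Ca,20 mg,17.8,5.7,-4.2,59.2
SN,20 mg,28.4,9.0,25.6,49.7
GP,20 mg,17.6,1.5,-3.2,19.7
Pu,40 mg,19.6,5.3,36.4,7.7
VSt,40 mg,27.6,8.2,22.6,20.3
Ca,40 mg,13.4,5.3,24.8,26.7
SN,40 mg,27.2,13.6,40.8,58.6
GP,40 mg,14.2,11.1,66.6,32.4
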