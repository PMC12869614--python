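species,agent,tissue,t1_0_ms,r1,ve
dog,Gd-EOB-DTPA,liver,581,14.6,0.23
dog,Gd-EOB-DTPA,spleen,1172,7.3,0.43
dog,Gd-EOB-DTPA,blood,1480,7.3,
dog,Gd-BT-DO3A,liver,581,5.2,0.23
dog,Gd-BT-DO3A,spleen,1172,5.3,0.43
dog,Gd-BT-DO3A,blood,1480,5.3,
pig,Gd-EOB-DTPA,liver,581,14.6,0.23
pig,Gd-EOB-DTPA,spleen,1172,6.9,0.43
pig,Gd-EOB-DTPA,blood,1480,6.9,
pig,Gd-BOPTA,liver,581,6.3,0.23
pig,Gd-BOPTA,spleen,1172,6.7,0.43
pig,Gd-BOPTA,blood,1480,6.7,
pig,Gd-DTPA,liver,581,3.4,0.23
pig,Gd-DTPA,spleen,1172,4.3,0.43
pig,Gd-DTPA,blood,1480,4.3,
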