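region_id,name,macro_region
1,Cairo,urban_governorates
2,Alexandria,urban_governorates
3,Port Said,urban_governorates
4,Suez,urban_governorates
5,Damietta,lower_egypt
6,Dakahlia,lower_egypt
7,Sharqia,lower_egypt
8,Qalyubia,lower_egypt
9,Kafr El Sheikh,lower_egypt
10,Gharbia,lower_egypt
11,Monufia,lower_egypt
12,Beheira,lower_egypt
13,Ismailia,lower_egypt
14,Giza,upper_egypt
15,Beni Suef,upper_egypt
16,Faiyum,upper_egypt
17,Minya,upper_egypt
18,Asyut,upper_egypt
19,Sohag,upper_egypt
20,Qena,upper_egypt
21,Aswan,upper_egypt
22,Luxor,upper_egypt
23,Red Sea,frontier
24,New Valley,frontier
25,Matrouh,frontier
26,North Sinai,frontier
27,South Sinai,frontier
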